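row_index,label,codes
1,"Low fat milk, plain and flavored",1004;1006;1204;1206
2,Cheese,1602
3,"Yogurt, whole/reduced",1802
4,"Yogurt, low fat/non-fat",1804
5,Nuts and seeds,2804
6,"Muffins, biscuits",4402
7,Potato chips,5002
8,Corn chips,5004;5008
9,Popcorn,5006
10,Crackers,5202;5204
11,Cereal bars,5402
12,Nutrition bars,5404
13,"Cakes, cookies, brownies",5502;5504;5506
14,"Candy, chocolate",5702
15,"Candy, fruit",5704
16,Ice cream,5802
17,Pudding/dairy dessert,5804
18,Ices,5806
19,"Apples, bananas, berries",6002;6004;6010
20,"Fruit, dried",6016
21,Fruit salad,6018
22,"Citrus, apple, and other juices",7002;7004;7006
23,Sugar sweetened sodas,7202
24,Fruit based soft drinks,7204
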