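item_id,name,kind,attached_to,serv_small_g,serv_med_g,serv_large_g,carb_g,protein_g,fat_g,sugars_g,fiber_g,sodium_mg
apple,Apples or pears,food,,70,140,210,14,0.3,0.2,10,2.4,1
banana,Bananas,food,,60,118,180,23,1.1,0.3,12,2.6,1
broccoli,Broccoli or other greens,food,,45,90,180,4.2,2.8,0.4,1.7,2.6,33
rice,Cooked rice,food,,79,158,316,28,2.7,0.3,0.1,0.4,1
oatmeal,Cooked oatmeal,food,,117,234,351,12,2.5,1.5,0.5,1.7,4
chicken,Roasted chicken,food,,56,112,168,0,31,3.6,0,0,74
beef,Beef roast or steak,food,,56,112,168,0,26,15,0,0,72
salmon,Baked or grilled fish,food,,57,113,170,0,22,12,0,0,59
eggs,Eggs,food,,50,100,150,1.1,12.6,9.5,1.1,0,124
milk,Milk as a beverage,beverage,,122,244,488,4.8,3.3,3.3,4.8,0,44
beans,Cooked dried beans,food,,90,180,260,23,9,0.5,0.3,6.4,1
coffee,"Coffee, brewed",beverage,,240,360,480,0,0.1,0,0,0,2
potato,Baked or boiled potatoes,food,,75,150,300,17,2,0.1,0.8,2.2,6
walnuts,"Nuts, unsalted",food,,14,28,56,14,15,65,2.6,6.7,2
olive_oil,Olive or vegetable oil,food,,5,14,28,0,0,100,0,0,2
butter,Butter,food,,5,14,28,0.1,0.9,81,0.1,0,643
sugar,Sugar added to food,food,,4,8,12,100,0,0,100,0,0
cheddar,Natural cheese,food,,28,56,84,1.3,25,33,0.5,0,621
ham,Ham or cured pork,food,,56,84,112,1.5,21,4,1.5,0,1200
canned_peaches,Canned peaches,food,,100,200,300,14,0.5,0.1,13,1.3,4
beer,Beer,beverage,,355,473,710,3.6,0.5,0,0,0,4
white_bread,White or wheat bread,food,,25,50,75,49,9,3.2,5,2.7,490
cookies,"Cookies, cakes or pies",food,,28,56,84,68,5,23,30,2,360
cola,Regular soft drinks,beverage,,355,473,710,10.6,0,0,10.6,0,4
fruit_punch,Fruit drinks or punch,beverage,,240,360,480,12,0,0,11.5,0,10
chips,Potato or corn chips,food,,28,42,84,53,7,34,0.3,4.4,525
candy,Candy,food,,20,40,60,92,0,0.2,80,0,15
ice_cream,Ice cream,food,,66,132,198,24,3.5,11,21,0.7,80
breakfast_cereal,Ready-to-eat cereal,food,,30,60,90,84,7,2.7,36,7,500
hot_dog,Hot dogs or sausages,food,,48,96,144,4,11,26,1,0,1090
pizza,Pizza or other ready meals,food,,107,214,321,33,11,10,3.6,2.3,600
margarine,Margarine on bread,condiment,white_bread,5,10,15,0.7,0.2,80,0.5,0,800
salad_dressing,Salad dressing,condiment,broccoli,15,30,45,16,1,45,14,0,900
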