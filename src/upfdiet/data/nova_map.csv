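item_id,nova_group,nova_subgroup,note
apple,1,fruits,fresh fruit; unprocessed
banana,1,fruits,fresh fruit; unprocessed
broccoli,1,vegetables,fresh or frozen vegetable
rice,1,grains,plain cooked grain
oatmeal,1,grains,plain cooked grain
chicken,1,poultry,plain roasted meat
beef,1,red_meat,plain cooked meat
salmon,1,fish_seafood,plain cooked fish
eggs,1,eggs,whole egg
milk,1,milk_plain_yogurt,plain fluid milk
beans,1,legumes,plain cooked legume
coffee,1,coffee_tea,brewed; no additions counted here
potato,1,roots_tubers,plain cooked tuber
walnuts,1,nuts_seeds,unsalted nuts
olive_oil,2,vegetable_oils,culinary ingredient
butter,2,butter_cream,culinary ingredient
sugar,2,table_sugar,culinary ingredient
cheddar,3,cheese,processed with salt and cultures
ham,3,cured_meat_fish,salted and cured
canned_peaches,3,canned_fruits_vegetables,canned in syrup
beer,3,beer_wine,fermented beverage
white_bread,4,breads,US commercial bread; industrially formulated
cookies,4,cakes_cookies_pies,industrial baked goods
cola,4,soft_drinks,sweetened carbonated beverage
fruit_punch,4,fruit_drinks,reconstituted sweetened drink
chips,4,salty_snacks,extruded or fried snack
candy,4,candy_confectionery,confectionery
ice_cream,4,ice_cream_desserts,industrial frozen dessert
breakfast_cereal,4,breakfast_cereals,extruded fortified cereal
hot_dog,4,reconstituted_meat,reconstituted meat product
pizza,4,ready_meals,ready-to-heat dish
margarine,4,sauces_dressings,industrial fat spread
salad_dressing,4,sauces_dressings,industrial dressing
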