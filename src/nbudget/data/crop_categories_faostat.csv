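crop,source,category
Wheat,faostat-like,Wheat
Barley,faostat-like,Barley
Maize,faostat-like,Grain maize
Oats,faostat-like,Other cereals
Rye,faostat-like,Other cereals
Triticale,faostat-like,Other cereals
Sorghum,faostat-like,Other cereals
Millet,faostat-like,Other cereals
Buckwheat,faostat-like,Other cereals
Canary seed,faostat-like,Other cereals
Mixed grain,faostat-like,Other cereals
Cereals nes,faostat-like,Other cereals
Rapeseed,faostat-like,Oilseeds
Sunflower seed,faostat-like,Oilseeds
Soybeans,faostat-like,Oilseeds
Linseed,faostat-like,Oilseeds
Hempseed,faostat-like,Oilseeds
Sesame seed,faostat-like,Oilseeds
Poppy seed,faostat-like,Oilseeds
Mustard seed,faostat-like,Oilseeds
Safflower seed,faostat-like,Oilseeds
Castor oil seed,faostat-like,Oilseeds
Groundnuts,faostat-like,Oilseeds
Cottonseed,faostat-like,Oilseeds
Melonseed,faostat-like,Oilseeds
Karite nuts,faostat-like,Oilseeds
Oilseeds nes,faostat-like,Oilseeds
Potatoes,faostat-like,Potatoes
Sugar beet,faostat-like,Sugar beet
Beans dry,faostat-like,Pulses
Peas dry,faostat-like,Pulses
Chick peas,faostat-like,Pulses
Lentils,faostat-like,Pulses
Broad beans dry,faostat-like,Pulses
Vetches,faostat-like,Pulses
Lupins,faostat-like,Pulses
Cow peas dry,faostat-like,Pulses
Pulses nes,faostat-like,Pulses
Tomatoes,faostat-like,Vegetables and other
Onions dry,faostat-like,Vegetables and other
Onions green,faostat-like,Vegetables and other
Garlic,faostat-like,Vegetables and other
Leeks,faostat-like,Vegetables and other
Cabbages,faostat-like,Vegetables and other
Cauliflowers and broccoli,faostat-like,Vegetables and other
Lettuce and chicory,faostat-like,Vegetables and other
Spinach,faostat-like,Vegetables and other
Artichokes,faostat-like,Vegetables and other
Asparagus,faostat-like,Vegetables and other
Carrots and turnips,faostat-like,Vegetables and other
Cucumbers and gherkins,faostat-like,Vegetables and other
Eggplants,faostat-like,Vegetables and other
Chillies and peppers green,faostat-like,Vegetables and other
Pumpkins squash and gourds,faostat-like,Vegetables and other
Beans green,faostat-like,Vegetables and other
Peas green,faostat-like,Vegetables and other
Broad beans green,faostat-like,Vegetables and other
String beans,faostat-like,Vegetables and other
Mushrooms and truffles,faostat-like,Vegetables and other
Watermelons,faostat-like,Vegetables and other
Melons other,faostat-like,Vegetables and other
Strawberries,faostat-like,Vegetables and other
Vegetables fresh nes,faostat-like,Vegetables and other
Sugar cane,faostat-like,Vegetables and other
Tobacco,faostat-like,Vegetables and other
Hops,faostat-like,Vegetables and other
Flax fibre,faostat-like,Vegetables and other
Hemp fibre,faostat-like,Vegetables and other
Cotton lint,faostat-like,Vegetables and other
Chicory roots,faostat-like,Vegetables and other
Sweet potatoes,faostat-like,Vegetables and other
Roots and tubers nes,faostat-like,Vegetables and other
Anise badian fennel,faostat-like,Vegetables and other
Peppermint,faostat-like,Vegetables and other
Pyrethrum,faostat-like,Vegetables and other
Spices nes,faostat-like,Vegetables and other
Seed cotton,faostat-like,Vegetables and other
Taro,faostat-like,Vegetables and other
Yams,faostat-like,Vegetables and other
Olives,faostat-like,Olives
Grapes,faostat-like,Grapes
Apples,faostat-like,Other permanent crops
Pears,faostat-like,Other permanent crops
Quinces,faostat-like,Other permanent crops
Apricots,faostat-like,Other permanent crops
Cherries sour,faostat-like,Other permanent crops
Cherries sweet,faostat-like,Other permanent crops
Peaches and nectarines,faostat-like,Other permanent crops
Plums and sloes,faostat-like,Other permanent crops
Stone fruit nes,faostat-like,Other permanent crops
Pome fruit nes,faostat-like,Other permanent crops
Figs,faostat-like,Other permanent crops
Oranges,faostat-like,Other permanent crops
Lemons and limes,faostat-like,Other permanent crops
Tangerines mandarins,faostat-like,Other permanent crops
Grapefruit,faostat-like,Other permanent crops
Citrus fruit nes,faostat-like,Other permanent crops
Bananas,faostat-like,Other permanent crops
Dates,faostat-like,Other permanent crops
Kiwi fruit,faostat-like,Other permanent crops
Persimmons,faostat-like,Other permanent crops
Avocados,faostat-like,Other permanent crops
Pineapples,faostat-like,Other permanent crops
Pomegranates,faostat-like,Other permanent crops
Fruit fresh nes,faostat-like,Other permanent crops
Berries nes,faostat-like,Other permanent crops
Currants,faostat-like,Other permanent crops
Gooseberries,faostat-like,Other permanent crops
Raspberries,faostat-like,Other permanent crops
Blueberries,faostat-like,Other permanent crops
Cranberries,faostat-like,Other permanent crops
Almonds,faostat-like,Other permanent crops
Walnuts,faostat-like,Other permanent crops
Hazelnuts,faostat-like,Other permanent crops
Chestnut,faostat-like,Other permanent crops
Pistachios,faostat-like,Other permanent crops
Nuts nes,faostat-like,Other permanent crops
Carobs,faostat-like,Other permanent crops
Tea,faostat-like,Other permanent crops
Coffee green,faostat-like,Other permanent crops
Other fibre crops,faostat-like,Other permanent crops
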