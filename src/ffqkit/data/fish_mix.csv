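fish_class,description,grams
white,"Plaice, fried in batter",50
white,"Cod, baked fillets",30
white,"Haddock, fried in crumbs",30
white,"Fish fingers, grilled",20
other,"Tuna, canned in brine",60
other,"Salmon fish cakes, homemade",12
other,"Salmon, pink, canned",10
other,"Trout, brown",8
other,"Salmon, steamed",5
other,"Sardines, canned in oil",5
other,"Pilchards, canned in tomato sauce",5
other,"Sardines, canned in tomato sauce",3
shellfish,"Scampi, breadcrumbed and fried",43
shellfish,"Crab, canned",21
shellfish,"Mussels, boiled",10
shellfish,"Prawns, boiled",15
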