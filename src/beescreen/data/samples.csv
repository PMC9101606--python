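code,name,form,groups,dose_text,grams_per_day
FS-01,Ampoules with royal jelly and honey,Ampoules,RG;HO,1 ampoule = 10 mL ≈ 10 g,10
FS-02,Ampoules with royal jelly for children,Ampoules,RG,1 ampoule = 9 mL = 10 g,10
FS-03,Ampoules with royal jelly,Ampoules,RG,1 ampoule = 9 mL = 10 g,10
FS-04,Royal jelly ampoules,Ampoules,RG,1 ampoule = 10 mL = 10 g,10
FS-05,Royal jelly ampoules for children,Ampoules,RG,1 ampoule = 10 mL ≈ 10 g,10
FS-06,Capsules with royal jelly,Capsules,RG,1 capsule = 0.37 g,0.37
FS-07,Royal jelly pastilles with vitamin C,Pastilles,RG,1 pastille = 1.24 g,1.24
FS-08,Royal jelly pastilles with sweeteners,Pastilles,RG,4 pastilles = 3.50 g,3.5
FS-09,Royal jelly pastilles,Pastilles,RG,2 pastilles = 2.50 g,2.5
FS-10,"Syrup with honey, royal jelly and propolis",Syrups,RG,30 mL ≈ 30 g,30
FS-11,"Food supplement based on propolis, honey and royal jelly",Syrups,RG,2 teaspoons = 10 mL ≈ 10 g,10
FS-12,Liquid food supplement with royal jelly and vitamin C,Liquid food supplements,RG,15 mL ≈ 15 g,15
FS-13,Liquid food supplement with royal jelly,Liquid food supplements,RG,20 mL ≈ 20 g,20
FS-14,Syrup with royal jelly and honey,Syrups,RG,25 mL ≈ 25 g,25
FS-15,Product with honey and supplements,Other forms,RG;HO,2 teaspoons = 10 g,10
FS-16,Propolis drops,Drops,PR,45 drops ≈ 1.35 mL ≈ 1.35 g,1.35
FS-17,Propolis drops,Drops,PR,60 drops ≈ 1.80 mL ≈ 1.80 g,1.8
FS-18,Propolis drops 15%,Drops,PR,50 drops = 1.35 mL ≈ 1.35 g,1.35
FS-19,Non-alcoholic propolis drops,Drops,PR,120 drops ≈ 3.60 mL ≈ 3.60 g,3.6
FS-20,Propolis drops,Drops,PR,125 drops = 3.75 mL ≈ 3.75 g,3.75
FS-21,Non-alcoholic drops with propolis and echinacea,Drops,PR,60 drops = 3 mL ≈ 3 g,3
FS-22,Capsules with propolis,Capsules,PR,4 capsules = 1.60 g,1.6
FS-23,Propolis pastilles,Pastilles,PR,5 pastilles = 10 g,10
FS-24,"Pastilles with propolis, vitamin C and zinc",Pastilles,PR,5 pastilles = 12.50 g,12.5
FS-25,Pastilles with propolis and vitamin C,Pastilles,PR,5 pastilles = 17.50 g,17.5
FS-26,"Syrup with propolis, honey and myrtle",Syrups,PR,10 mL ≈ 10 g,10
FS-27,"Syrup with honey, propolis and wild thyme",Syrups,PR;HO,30 mL ≈ 30 g,30
FS-28,"Syrup with propolis, honey, marshmallow, thyme and vitamins",Syrups,PR;HO,30 mL = 41.70 g,41.7
FS-29,Propolis spray,Sprays,PR,1.1 mL ≈ 1.10 g,1.1
FS-30,Propolis spray for children,Sprays,PR,0.55 mL ≈ 0.55 g,0.55
FS-31,Propolis water spray with vitamin B3,Sprays,PR,1 mL = 1.20 g,1.2
FS-32,Propolis solution in spray,Sprays,PR,1.68 mL ≈ 1.68 g,1.68
FS-33,Non-alcoholic propolis solution with peppermint in spray,Sprays,PR,0.5 mL ≈ 0.50 g,0.5
FS-34,Peppermint-flavoured chewable tablets,Tablets,PR,3 tablets = 3 g,3
FS-35,Honey-flavoured chewable tablets,Tablets,PR,3 tablets = 3 g,3
FS-36,Candies with propolis and vitamins A and C,Tablets,PR,5 candies = 3.50 g,3.5
FS-37,"Chewable tablets for children, with sweetener, with the addition of vitamin C",Tablets,PR,3 tablets = 1.65 g,1.65
FS-38,Effervescent tablets with propolis and vitamin C,Tablets,PR,2 tablets = 9 g,9
FS-39,"Liquid food supplement for children and adults, with marshmallow and propolis",Liquid food supplements,PR,45 mL ≈ 45 g,4.5
FS-40,Liquid food supplement with propolis,Liquid food supplements,PR,22.5 mL ≈ 22.50 g,22.5
FS-41,Liquid food supplement with thyme and propolis,Liquid food supplements,PR;HO,30 mL = 35.40 g,35.4
FS-42,"Pastilles with sage, chamomile and honey",Pastilles,HO,6 pastilles = 15 g,15
FS-43,"Syrup with honey, propolis and marshmallow",Syrups,HO,30 mL ≈ 30 g,30
FS-44,"Syrup with honey, iron and vitamin C",Syrups,HO,10 mL ≈ 10 g,10
FS-45,"Syrup for children with propolis, honey and supplements",Syrups,HO,10 mL ≈ 10 g,10
FS-46,Syrup with honey and supplements,Syrups,HO,3 teaspoons = 15 g,15
FS-47,Liquid food supplement with honey and thyme,Liquid food supplements,HO,15 mL ≈ 15 g,15
FS-48,Honey with propolis and thyme,Other forms,HO,5 teaspoons = 32.50 g,32.5
FS-49,"Product with honey, propolis, sage, wild thyme, lungwort and nettle",Other forms,HO,15 g,15
FS-50,Honey with supplements,Other forms,HO,15 g,15
FS-51,Honey-based product with lemon balm and valerian,Other forms,HO,15 g,15
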