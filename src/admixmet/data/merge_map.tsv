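sub_pathway	cluster_label
Diacylglycerol	Diacylglycerol and monoacylglycerol
Monoacylglycerol	Diacylglycerol and monoacylglycerol
Plasmalogen	Plasmalogen and lysoplasmalogen
Lysoplasmalogen	Plasmalogen and lysoplasmalogen
Sphingolipid Metabolism	Sphingolipid metabolism and ceramides
Ceramides	Sphingolipid metabolism and ceramides
Urea cycle; Arginine and Proline Metabolism	Urea cycle; arginine and proline metabolism
Urea Cycle	Urea cycle; arginine and proline metabolism
Arginine Metabolism	Urea cycle; arginine and proline metabolism
Proline Metabolism	Urea cycle; arginine and proline metabolism
Primary Bile Acid Metabolism	Primary and secondary bile acid metabolism
Secondary Bile Acid Metabolism	Primary and secondary bile acid metabolism
Tocopherol Metabolism	Cofactors and vitamins
Nicotinate and Nicotinamide Metabolism	Cofactors and vitamins
Cofactors and Vitamins	Cofactors and vitamins
Pyrimidine Metabolism	Pyrimidine and purine metabolism
Purine Metabolism	Pyrimidine and purine metabolism
Phospholipid Metabolism	PC, PE, PI, lysophospholipid and phospholipid metabolism
Lysophospholipid	PC, PE, PI, lysophospholipid and phospholipid metabolism
Fatty Acid Metabolism (Acyl Carnitine)	Fatty acid metabolism (acyl carnitine)
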