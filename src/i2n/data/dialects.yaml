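# Built-in column maps for the four supported food-composition CSV dialects.
#
# Each dialect maps source column names onto the unified record model:
#   id / description / group  -> identifying fields
#   energy                    -> energy column and its unit (kcal or kJ;
#                                kJ is converted to kcal at load time)
#   nutrients                 -> unified nutrient name -> {column, unit}
#   portions                  -> ordered (label column, gram-weight column)
#                                pairs of the portion-weight table
#
# The schemas are modelled on the public USDA Standard Reference abbreviated
# file, FNDDS survey exports, the USDA Branded Food Products download, and
# FAO food-composition tables. Additional dialects can be supplied at run
# time as a YAML file with the same shape.

sr:
  id: NDB_No
  description: Shrt_Desc
  group: FdGrp_Desc
  energy: {column: Energ_Kcal, unit: kcal}
  nutrients:
    protein: {column: "Protein_(g)", unit: g}
    fat: {column: "Lipid_Tot_(g)", unit: g}
    carbohydrate: {column: "Carbohydrt_(g)", unit: g}
    fiber: {column: "Fiber_TD_(g)", unit: g}
    calcium: {column: "Calcium_(mg)", unit: mg}
    iron: {column: "Iron_(mg)", unit: mg}
    vitamin_c: {column: "Vit_C_(mg)", unit: mg}
  portions:
    - {label: GmWt_Desc1, weight: GmWt_1}
    - {label: GmWt_Desc2, weight: GmWt_2}
    - {label: GmWt_Desc3, weight: GmWt_3}
    - {label: GmWt_Desc4, weight: GmWt_4}

fndds:
  id: "Food code"
  description: "Main food description"
  group: "WWEIA Category description"
  energy: {column: "Energy (kcal)", unit: kcal}
  nutrients:
    protein: {column: "Protein (g)", unit: g}
    fat: {column: "Total Fat (g)", unit: g}
    carbohydrate: {column: "Carbohydrate (g)", unit: g}
    fiber: {column: "Fiber, total dietary (g)", unit: g}
    calcium: {column: "Calcium (mg)", unit: mg}
    iron: {column: "Iron (mg)", unit: mg}
    vitamin_c: {column: "Vitamin C (mg)", unit: mg}
  portions:
    - {label: "Portion description 1", weight: "Portion weight 1 (g)"}
    - {label: "Portion description 2", weight: "Portion weight 2 (g)"}
    - {label: "Portion description 3", weight: "Portion weight 3 (g)"}
    - {label: "Portion description 4", weight: "Portion weight 4 (g)"}

branded:
  id: fdc_id
  description: product_name
  group: branded_food_category
  energy: {column: energy_kj, unit: kJ}
  nutrients:
    protein: {column: protein_g, unit: g}
    fat: {column: fat_g, unit: g}
    carbohydrate: {column: carbohydrate_g, unit: g}
    fiber: {column: fiber_g, unit: g}
    calcium: {column: calcium_mg, unit: mg}
    iron: {column: iron_mg, unit: mg}
    vitamin_c: {column: vitamin_c_mg, unit: mg}
  portions:
    - {label: household_serving_1, weight: serving_gram_weight_1}
    - {label: household_serving_2, weight: serving_gram_weight_2}
    - {label: household_serving_3, weight: serving_gram_weight_3}
    - {label: household_serving_4, weight: serving_gram_weight_4}

fao:
  id: Code
  description: "Food name"
  group: "Food group"
  energy: {column: "Energy (kcal)", unit: kcal}
  nutrients:
    protein: {column: "Protein (g)", unit: g}
    fat: {column: "Fat (g)", unit: g}
    carbohydrate: {column: "Available carbohydrate (g)", unit: g}
    fiber: {column: "Dietary fibre (g)", unit: g}
    calcium: {column: "Ca (mg)", unit: mg}
    iron: {column: "Fe (mg)", unit: mg}
    vitamin_c: {column: "Vitamin C (mg)", unit: mg}
  portions:
    - {label: "Measure 1", weight: "Measure weight 1 (g)"}
    - {label: "Measure 2", weight: "Measure weight 2 (g)"}
    - {label: "Measure 3", weight: "Measure weight 3 (g)"}
    - {label: "Measure 4", weight: "Measure weight 4 (g)"}
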