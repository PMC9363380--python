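# 17-item energy-reduced Mediterranean diet screener criteria.
# Each item is a binary criterion on one dietary variable; an item scores 1
# point when the criterion is met.  `op` is one of ge/gt/le/lt/between.
# `between` uses inclusive bounds; bounds_by_sex gives (low, high) per sex.
#
# Two presets ship:
#   printed        - the screener items as commonly printed, including the
#                    white-bread item in its ">= 1 serving/day" direction.
#   reversed_breads - identical except items 14 and 16 flip direction
#                    (white bread, refined pasta/rice), for sensitivity runs.
schema_version: 1
presets:
  printed:
    - {item: 1,  label: "Olive oil as the only cooking fat",                    variable: evoo_only,             op: ge, threshold: 0.5}
    - {item: 2,  label: "Vegetables >= 2 units/day",                            variable: veg_units_day,         op: ge, threshold: 2}
    - {item: 3,  label: "Fruit >= 3 units/day",                                 variable: fruit_units_day,       op: ge, threshold: 3}
    - {item: 4,  label: "Red or processed meat <= 1 serving/week",              variable: red_meat_serv_wk,      op: le, threshold: 1}
    - {item: 5,  label: "Butter, margarine or cream < 1 serving/week",          variable: butter_serv_wk,        op: lt, threshold: 1}
    - {item: 6,  label: "Sugar-sweetened beverage or juice < 1 serving/week",   variable: ssb_serv_wk,           op: lt, threshold: 1}
    - {item: 7,  label: "Legumes >= 3 servings/week",                           variable: legume_serv_wk,        op: ge, threshold: 3}
    - {item: 8,  label: "Fish or shellfish >= 3 servings/week",                 variable: fish_serv_wk,          op: ge, threshold: 3}
    - {item: 9,  label: "Commercial sweets or pastries < 3 times/week",         variable: sweets_serv_wk,        op: lt, threshold: 3}
    - {item: 10, label: "Nuts >= 3 servings/week",                              variable: nuts_serv_wk,          op: ge, threshold: 3}
    - {item: 11, label: "Preference for lean meats",                            variable: lean_meat_pref,        op: ge, threshold: 0.5}
    - {item: 12, label: "Sofrito sauce >= 2 times/week",                        variable: sofrito_serv_wk,       op: ge, threshold: 2}
    - {item: 13, label: "Non-caloric sweeteners preferred in beverages",        variable: artif_sweetener_pref,  op: ge, threshold: 0.5}
    - {item: 14, label: "White bread >= 1 serving/day",                         variable: white_bread_serv_day,  op: ge, threshold: 1}
    - {item: 15, label: "Whole-grain cereals or pasta >= 5 times/week",         variable: wholegrain_serv_wk,    op: ge, threshold: 5}
    - {item: 16, label: "Refined pasta or white rice < 3 times/week",           variable: refined_grain_serv_wk, op: lt, threshold: 3}
    - {item: 17, label: "Moderate wine (2-3 glasses/day men, 1-2 women)",       variable: wine_glasses_day,      op: between, bounds_by_sex: {male: [2, 3], female: [1, 2]}}
  reversed_breads:
    - {item: 1,  label: "Olive oil as the only cooking fat",                    variable: evoo_only,             op: ge, threshold: 0.5}
    - {item: 2,  label: "Vegetables >= 2 units/day",                            variable: veg_units_day,         op: ge, threshold: 2}
    - {item: 3,  label: "Fruit >= 3 units/day",                                 variable: fruit_units_day,       op: ge, threshold: 3}
    - {item: 4,  label: "Red or processed meat <= 1 serving/week",              variable: red_meat_serv_wk,      op: le, threshold: 1}
    - {item: 5,  label: "Butter, margarine or cream < 1 serving/week",          variable: butter_serv_wk,        op: lt, threshold: 1}
    - {item: 6,  label: "Sugar-sweetened beverage or juice < 1 serving/week",   variable: ssb_serv_wk,           op: lt, threshold: 1}
    - {item: 7,  label: "Legumes >= 3 servings/week",                           variable: legume_serv_wk,        op: ge, threshold: 3}
    - {item: 8,  label: "Fish or shellfish >= 3 servings/week",                 variable: fish_serv_wk,          op: ge, threshold: 3}
    - {item: 9,  label: "Commercial sweets or pastries < 3 times/week",         variable: sweets_serv_wk,        op: lt, threshold: 3}
    - {item: 10, label: "Nuts >= 3 servings/week",                              variable: nuts_serv_wk,          op: ge, threshold: 3}
    - {item: 11, label: "Preference for lean meats",                            variable: lean_meat_pref,        op: ge, threshold: 0.5}
    - {item: 12, label: "Sofrito sauce >= 2 times/week",                        variable: sofrito_serv_wk,       op: ge, threshold: 2}
    - {item: 13, label: "Non-caloric sweeteners preferred in beverages",        variable: artif_sweetener_pref,  op: ge, threshold: 0.5}
    - {item: 14, label: "White bread < 1 serving/day",                          variable: white_bread_serv_day,  op: lt, threshold: 1}
    - {item: 15, label: "Whole-grain cereals or pasta >= 5 times/week",         variable: wholegrain_serv_wk,    op: ge, threshold: 5}
    - {item: 16, label: "Refined pasta or white rice >= 3 times/week",          variable: refined_grain_serv_wk, op: ge, threshold: 3}
    - {item: 17, label: "Moderate wine (2-3 glasses/day men, 1-2 women)",       variable: wine_glasses_day,      op: between, bounds_by_sex: {male: [2, 3], female: [1, 2]}}
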