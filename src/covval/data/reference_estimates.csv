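indicator_id,method,gold_n,gold_prevalence_pct,comparison_n,dont_know_pct,comparison_prevalence_pct,matched_pairs_n,agreement_pct,five_per_cell,sensitivity_pct,specificity_pct,auc,inflation_factor,criteria_met
main_provider_skilled,exit,1889,10,1775,0,32,1775,72,yes,67,72,0.70,3.04,AUC
main_provider_skilled,followup,445,13,426,0,48,426,55,yes,62,54,0.58,3.76,none
main_provider_skilled,register,1516,12,1327,0,12,1327,97,yes,92,98,0.95,1.05,"AUC,IF"
multiple_providers,exit,1869,57,1774,0,58,1755,93,yes,95,90,0.93,1.02,"AUC,IF"
multiple_providers,followup,444,55,426,0,80,418,60,yes,86,26,0.56,1.45,none
support_person_present,exit,1127,35,1075,0,57,1067,75,yes,97,64,0.80,1.65,AUC
support_person_present,followup,443,31,426,0,82,419,41,yes,88,21,0.54,2.64,none
adolescent_birth,register,1516,20,1472,0,20,1463,98,yes,95,99,0.97,0.98,"AUC,IF"
grand_multipara,register,1515,47,1474,0,49,1471,93,yes,95,91,0.93,1.06,"AUC,IF"
allowed_move,exit,712,78,1075,1,71,674,84,yes,92,57,0.75,1.04,"AUC,IF"
allowed_drink_eat,exit,712,91,1075,1,92,674,91,yes,98,25,0.61,1.05,IF
preferred_position,exit,773,52,1075,1,75,691,81,yes,95,63,0.79,1.29,AUC
allowed_support_person,exit,1885,63,1773,1,59,1757,85,yes,85,85,0.85,0.94,"AUC,IF"
allowed_support_person,followup,443,60,426,1,67,422,57,yes,71,36,0.53,1.14,IF
handwashing_soap,exit,1872,30,1775,16,40,1492,81,yes,,,,,
handwashing_soap,followup,444,19,426,16,77,359,26,no,,,,,
gloves_worn,exit,1872,75,1775,0,98,1769,75,yes,98,2,0.50,1.30,none
gloves_worn,followup,444,90,426,1,98,419,90,no,,,,,
partograph_used,register,1516,21,1308,0,39,1306,79,yes,95,75,0.84,1.92,AUC
blood_pressure_taken,exit,1515,31,1435,0,34,1429,92,yes,91,92,0.91,1.10,"AUC,IF"
blood_pressure_taken,followup,444,22,426,2,58,417,56,yes,82,48,0.65,2.62,none
episiotomy,exit,1504,1,1435,0,2,1429,98,no,,,,,
episiotomy,followup,444,1,426,2,9,424,91,no,,,,,
uterotonic,exit,1867,96,1775,0,94,1763,93,yes,95,33,0.64,0.98,IF
uterotonic,followup,442,96,426,1,83,420,82,yes,84,26,0.55,0.88,IF
uterotonic,register,1501,96,1338,0,93,1332,90,no,,,,,
same_room,exit,1755,97,1775,1,96,1704,97,yes,98,40,0.69,1.00,IF
same_room,followup,427,95,426,0,88,406,85,no,,,,,
essential_newborn_care,exit,1889,42,1774,0,51,1774,87,yes,92,83,0.88,1.15,"AUC,IF"
essential_newborn_care,followup,445,36,445,0,64,445,60,yes,83,47,0.65,1.77,none
essential_newborn_care,register,1516,39,1297,0,95,1297,44,yes,97,6,0.52,2.46,none
newborn_dried,exit,1472,95,1435,2,94,1393,98,yes,99,68,0.83,1.00,"AUC,IF"
newborn_dried,followup,430,91,426,3,91,397,86,no,,,,,
skin_to_skin,exit,1759,77,1775,3,72,1681,94,yes,94,93,0.93,0.96,"AUC,IF"
skin_to_skin,followup,427,67,426,1,75,402,78,yes,90,52,0.71,1.15,"AUC,IF"
immediate_breastfeeding,exit,1744,49,1775,2,51,1686,90,yes,94,87,0.90,1.08,"AUC,IF"
immediate_breastfeeding,followup,424,42,426,0,67,404,62,yes,87,44,0.66,1.66,none
chlorhexidine_cord,exit,1425,85,1435,5,80,1323,95,yes,96,84,0.90,0.99,"AUC,IF"
baby_weighed,exit,1785,84,1774,9,80,1603,86,yes,,,,,
baby_weighed,followup,439,78,426,11,62,377,66,yes,,,,,
baby_weighed,register,1439,90,1421,0,94,1403,87,yes,95,16,0.55,1.04,IF
low_birthweight,exit,1604,5,1424,57,3,606,98,yes,,,,,
low_birthweight,register,1432,6,1338,0,17,1180,83,yes,62,85,0.73,3.22,AUC
preterm_birth,register,1515,2,1169,0,2,1167,99,no,,,,,
stillbirth,register,1516,3,1375,0,3,1365,99,yes,82,100,0.91,0.97,"AUC,IF"
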