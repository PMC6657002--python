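indicator_id,label,group,exit,followup,register,derivation,source_field,threshold,positive_meaning
main_provider_skilled,"Main provider - doctor, nurse, or midwife",skilled attendance & companionship,1,1,1,cadre_map,provider_cadre,,Main provider during labor and delivery was a doctor nurse or midwife
multiple_providers,More than one provider present at birth,skilled attendance & companionship,1,1,0,identity,multiple_providers,,More than one provider was present at the birth
support_person_present,Support person present at birth,skilled attendance & companionship,1,1,0,identity,support_person_present,,A support person was present at the birth
adolescent_birth,Maternal age at delivery (adolescent births),care for the woman - background,0,0,1,threshold_lt,age_years,20,Mother was younger than 20 years at delivery
grand_multipara,"Prior parity (4 or more births)",care for the woman - background,0,0,1,threshold_ge,parity,4,Mother had four or more prior births
allowed_move,Woman allowed to move and change position during labor,care for the woman - respectful care,1,0,0,identity,allowed_move,,Woman was allowed to move and change position during labor
allowed_drink_eat,Woman allowed to drink liquids and eat during labor,care for the woman - respectful care,1,0,0,identity,allowed_drink_eat,,Woman was allowed to drink liquids and eat during labor
preferred_position,Woman allowed to deliver in preferred position,care for the woman - respectful care,1,0,0,identity,preferred_position,,Woman was allowed to deliver in her preferred position
allowed_support_person,Woman allowed to have a support person at birth,care for the woman - respectful care,1,1,0,identity,allowed_support_person,,Woman was allowed to have a support person at the birth
handwashing_soap,Birth attendant washed hands with soap before examinations,care for the woman - respectful care,1,1,0,identity,handwashing_soap,,Birth attendant washed hands with soap before examinations
gloves_worn,Birth attendant wore gloves during examinations,care for the woman - respectful care,1,1,0,identity,gloves_worn,,Birth attendant wore gloves during examinations
partograph_used,Partograph used to monitor labor and delivery,care for the woman - respectful care,0,0,1,identity,partograph_used,,A partograph was used to monitor labor and delivery
blood_pressure_taken,Blood pressure taken - initial client assessment,care for the woman - clinical care,1,1,0,identity,blood_pressure_taken,,Blood pressure was taken at the initial client assessment
episiotomy,Episiotomy performed,care for the woman - clinical care,1,1,0,identity,episiotomy,,An episiotomy was performed
uterotonic,Prophylactic uterotonic administered during third stage of labor,care for the woman - clinical care,1,1,1,identity,uterotonic,,A prophylactic uterotonic was administered during the third stage of labor
same_room,Mother and newborn kept in same room after delivery,care for the newborn - immediate postnatal,1,1,0,identity,same_room,,Mother and newborn were kept in the same room after delivery
newborn_dried,Newborn immediately dried with a towel,care for the newborn - immediate postnatal,1,1,0,identity,newborn_dried,,Newborn was immediately dried with a towel
skin_to_skin,Newborn immediately placed skin-to-skin,care for the newborn - immediate postnatal,1,1,0,identity,skin_to_skin,,Newborn was immediately placed skin-to-skin on the mother
immediate_breastfeeding,Immediate initiation of breastfeeding,care for the newborn - immediate postnatal,1,1,0,identity,immediate_breastfeeding,,Breastfeeding was initiated immediately after birth
essential_newborn_care,Essential newborn care (composite),care for the newborn - immediate postnatal,1,1,1,composite,"immediate_breastfeeding,kept_warm",,Breastfeeding initiated and newborn kept warm within the dialect time window
chlorhexidine_cord,Chlorhexidine applied to newborn's cord,care for the newborn - immediate postnatal,1,0,0,identity,chlorhexidine_cord,,Chlorhexidine was applied to the newborn's cord to prevent infection
baby_weighed,Baby weighed at birth,care for the newborn - immediate postnatal,1,1,1,identity,baby_weighed,,Baby was weighed at birth
low_birthweight,"Low birthweight, <2500 g",care for the newborn - outcomes,1,0,1,threshold_lt,birthweight_g,2500,Birthweight below 2500 grams
preterm_birth,Pre-term birth,care for the newborn - outcomes,0,0,1,identity,preterm_birth,,Birth was pre-term
stillbirth,"Stillbirth, fresh or macerated",care for the newborn - outcomes,0,0,1,identity,stillbirth,,Baby was stillborn (fresh or macerated)
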