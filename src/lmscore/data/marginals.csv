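part,group,item_id,point,count
history,mild,inspiratory_sound,0,12
history,mild,inspiratory_sound,1,32
history,mild,inspiratory_sound,2,0
history,mild,cyanotic_spells,0,44
history,mild,cyanotic_spells,3,0
history,mild,interrupted_sleep,0,30
history,mild,interrupted_sleep,1,14
history,mild,interrupted_sleep,2,0
history,mild,growth,0,32
history,mild,growth,1,12
history,mild,growth,2,0
history,mild,choking,0,28
history,mild,choking,1,16
history,mild,choking,2,0
history,mild,regurgitation,0,34
history,mild,regurgitation,1,10
history,mild,regurgitation,2,0
history,mild,icu_admission,0,42
history,mild,icu_admission,1,2
history,mild,icu_admission,2,0
history,moderate,inspiratory_sound,0,5
history,moderate,inspiratory_sound,1,26
history,moderate,inspiratory_sound,2,17
history,moderate,cyanotic_spells,0,44
history,moderate,cyanotic_spells,3,4
history,moderate,interrupted_sleep,0,12
history,moderate,interrupted_sleep,1,30
history,moderate,interrupted_sleep,2,6
history,moderate,growth,0,10
history,moderate,growth,1,26
history,moderate,growth,2,12
history,moderate,choking,0,2
history,moderate,choking,1,42
history,moderate,choking,2,4
history,moderate,regurgitation,0,10
history,moderate,regurgitation,1,36
history,moderate,regurgitation,2,2
history,moderate,icu_admission,0,33
history,moderate,icu_admission,1,15
history,moderate,icu_admission,2,0
history,severe,inspiratory_sound,0,0
history,severe,inspiratory_sound,1,3
history,severe,inspiratory_sound,2,17
history,severe,cyanotic_spells,0,6
history,severe,cyanotic_spells,3,14
history,severe,interrupted_sleep,0,0
history,severe,interrupted_sleep,1,6
history,severe,interrupted_sleep,2,14
history,severe,growth,0,0
history,severe,growth,1,5
history,severe,growth,2,15
history,severe,choking,0,0
history,severe,choking,1,6
history,severe,choking,2,14
history,severe,regurgitation,0,0
history,severe,regurgitation,1,10
history,severe,regurgitation,2,10
history,severe,icu_admission,0,3
history,severe,icu_admission,1,11
history,severe,icu_admission,2,6
exam,moderate,growth_chart,0,0
exam,moderate,growth_chart,1,19
exam,moderate,growth_chart,2,29
exam,moderate,chest_retractions,0,11
exam,moderate,chest_retractions,1,13
exam,moderate,chest_retractions,2,20
exam,moderate,chest_retractions,3,4
exam,moderate,collapse_degree,0,16
exam,moderate,collapse_degree,1,17
exam,moderate,collapse_degree,2,15
exam,moderate,swallowing_fees,0,5
exam,moderate,swallowing_fees,1,16
exam,moderate,swallowing_fees,2,27
exam,moderate,developmental,0,11
exam,moderate,developmental,1,29
exam,moderate,developmental,2,8
exam,moderate,congenital_anomalies,0,26
exam,moderate,congenital_anomalies,1,21
exam,moderate,congenital_anomalies,2,1
exam,severe,growth_chart,0,0
exam,severe,growth_chart,1,1
exam,severe,growth_chart,2,19
exam,severe,chest_retractions,0,0
exam,severe,chest_retractions,1,6
exam,severe,chest_retractions,2,11
exam,severe,chest_retractions,3,3
exam,severe,collapse_degree,0,0
exam,severe,collapse_degree,1,14
exam,severe,collapse_degree,2,6
exam,severe,swallowing_fees,0,0
exam,severe,swallowing_fees,1,2
exam,severe,swallowing_fees,2,18
exam,severe,developmental,0,0
exam,severe,developmental,1,11
exam,severe,developmental,2,9
exam,severe,congenital_anomalies,0,12
exam,severe,congenital_anomalies,1,6
exam,severe,congenital_anomalies,2,2
investigation,moderate,echo,0,5
investigation,moderate,echo,1,10
investigation,moderate,echo,2,18
investigation,moderate,echo,3,2
investigation,moderate,overnight_oximetry,0,1
investigation,moderate,overnight_oximetry,1,10
investigation,moderate,overnight_oximetry,2,21
investigation,moderate,overnight_oximetry,3,3
investigation,moderate,synchronous_airway_lesion,0,21
investigation,moderate,synchronous_airway_lesion,1,10
investigation,moderate,synchronous_airway_lesion,2,4
investigation,moderate,gerd,0,6
investigation,moderate,gerd,1,11
investigation,moderate,gerd,2,18
investigation,severe,echo,0,8
investigation,severe,echo,1,3
investigation,severe,echo,2,6
investigation,severe,echo,3,3
investigation,severe,overnight_oximetry,0,0
investigation,severe,overnight_oximetry,1,0
investigation,severe,overnight_oximetry,2,14
investigation,severe,overnight_oximetry,3,6
investigation,severe,synchronous_airway_lesion,0,8
investigation,severe,synchronous_airway_lesion,1,5
investigation,severe,synchronous_airway_lesion,2,7
investigation,severe,gerd,0,0
investigation,severe,gerd,1,6
investigation,severe,gerd,2,14
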