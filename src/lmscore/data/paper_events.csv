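patient_id,visit_month,event_type,inspiratory_sound,cyanotic_spells,interrupted_sleep,growth,choking,regurgitation,icu_admission,growth_chart,chest_retractions,collapse_degree,swallowing_fees,developmental,congenital_anomalies,note
M001,1,reassessment,1,0,1,1,1,1,0,1,0,0,1,0,0,mild escalation to moderate band; exam < 4 so conservative management continues
M002,1,reassessment,1,0,1,1,1,1,0,1,0,0,1,0,0,mild escalation to moderate band; exam < 4 so conservative management continues
M003,2,reassessment,1,0,1,1,1,1,0,1,0,0,1,0,0,mild escalation to moderate band; exam < 4 so conservative management continues
M004,2,reassessment,1,0,1,1,1,1,0,1,0,0,1,0,0,mild escalation to moderate band; exam < 4 so conservative management continues
M005,3,reassessment,1,0,1,1,1,1,0,1,0,0,1,0,0,mild escalation to moderate band; exam < 4 so conservative management continues
D014,3,reassessment,2,3,2,2,1,1,1,,,,,,,watchful-waiting patient deteriorates to the severe band and undergoes supraglottoplasty
D025,1,postoperative_airway_compromise,,,,,,,,,,,,,,Down syndrome with macroglossia; compromised airway after supraglottoplasty requiring tracheostomy
S001,0,sal_tracheostomy,,,,,,,,,,,,,,subglottic stenosis grade II with bilateral vocal-cord paralysis; tracheostomy in addition to supraglottoplasty
S002,0,sal_tracheostomy,,,,,,,,,,,,,,subglottic stenosis grade II with bilateral vocal-cord paralysis; tracheostomy in addition to supraglottoplasty
S008,0,sal_tracheostomy,,,,,,,,,,,,,,tracheoesophageal fistula repair with supraglottoplasty and tracheostomy
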