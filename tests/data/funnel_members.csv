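member_id,age,gender,bmi,race,baseline_hba1c,self_efficacy,insulin_use,oral_meds,flu_vaccine,smoker,comms_pref,activity_interest,app_use_days,web_gap_days,smbg_check_days,coaching_sessions,active_days,food_logs,nutrition_nudge_yes_frac,content_nudge_yes_frac,observation_days,type2_diabetes,cgm_user
F000,50.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F001,51.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F002,52.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F003,53.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F004,54.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F005,55.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F006,56.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F007,57.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F008,58.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F009,59.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F010,60.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F011,61.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F012,62.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F013,63.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F014,64.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F015,65.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F016,66.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F017,67.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F018,68.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F019,69.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F020,50.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F021,51.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F022,52.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F023,53.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F024,54.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F025,55.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,75,1,0
F026,56.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,75,1,0
F027,57.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,75,1,0
F028,58.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,75,1,0
F029,59.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,75,1,0
F030,60.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,0,0
F031,61.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,0,0
F032,62.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,0,0
F033,63.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,0,0
F034,64.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,1
F035,65.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,1
F036,66.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,1
F037,67.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F038,68.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F039,69.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F040,50.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F041,51.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F042,52.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F043,53.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F044,54.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F045,55.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F046,56.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F047,57.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F048,58.0,male,30.0,white,8.5,medium,0,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
F049,59.0,female,30.0,white,8.5,medium,1,1,0,0,app,3.0,20,10.0,40.0,1.0,10.0,1.0,0.2,0.3,120,1,0
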