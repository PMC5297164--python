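respondent_id,group,sex,age_band,role,discipline,years_experience,qualification,academic
R01,EDr,Male,35-54,Emergency Physician,medical,16+,Medical Degree,no
R02,EDr,Male,35-54,Emergency Physician,medical,16+,Medical Degree,no
R03,EDr,Male,>55,Emergency Physician,medical,16+,Medical Degree,no
R04,SDr,Male,35-54,Stroke Doctor,medical,16+,"PhD, DN",yes
R05,SDr,Male,>55,Stroke Doctor,medical,16+,"PhD, DN",no
R06,SDr,Male,>55,Stroke Doctor,medical,16+,"PhD, DN",no
R07,EN,Male,<34,Emergency Nurse Specialist,nursing,11-15,Bachelor's Degree,no
R08,EN,Male,35-54,Emergency Nurse Specialist,nursing,16+,Master's Degree,no
R09,EN,Male,>55,Emergency Nurse Specialist,nursing,16+,Master's Degree,no
R10,SN,Female,35-54,Stroke Nurse Specialist,nursing,11-15,Master's Degree,no
R11,SN,Female,35-54,Stroke Nurse Specialist,nursing,16+,Master's Degree,no
R12,SN,Female,>55,Stroke Nurse Specialist,nursing,16+,"PhD, DN",yes
R13,SP,Female,<34,Speech Pathologist,speech pathology,5-10,Master's Degree,no
R14,SP,Female,35-54,Speech Pathologist,speech pathology,5-10,Master's Degree,no
R15,SP,Female,>55,Speech Pathologist,speech pathology,16+,"PhD, DN",no
R16,BM,Female,<34,Bed Manager,bed management,5-10,Bachelor's Degree,no
R17,BM,Female,35-54,Bed Manager,bed management,16+,Bachelor's Degree,no
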