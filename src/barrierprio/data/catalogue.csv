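behaviour_id,behaviour_name,barrier_id,barrier_description,eligible_groups
1,Triaged as ATS Category 1 or 2,1.1,Lack of stroke leadership,EN|EDr|SDr
1,Triaged as ATS Category 1 or 2,1.2,No hospital protocol for rapid stroke care,EN|EDr|SDr
1,Triaged as ATS Category 1 or 2,1.3,Resolving symptoms less likely to be triaged category 1/2,EN|EDr|SDr
1,Triaged as ATS Category 1 or 2,1.4,Staff inadequately trained in stroke symptoms,EN|EDr|SDr
1,Triaged as ATS Category 1 or 2,1.5,ED nurses do not perceive stroke as medical emergency,EN|EDr|SDr
1,Triaged as ATS Category 1 or 2,1.6,A validated stroke screen tool is not used,EN|EDr|SDr
2,Full assessment for rt-PA eligibility,2.1,Lack of clinical leadership for tPA,EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.2,Stressful and overburdened working conditions,EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.3,Disagreements between staff (ED and neurologists),EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.4,Physician lack of knowledge/experience with tPA,EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.5,Lack of staff continuity,EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.6,Delays in obtaining CT scans,EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.7,ED non-triage staff have poor recognition of stroke symptoms,EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.8,Lack of tPA protocol,EN|EDr|SN|SDr
2,Full assessment for rt-PA eligibility,2.9,Lack of teamwork,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.1,Delays associated with CT scan,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.2,ED staff don't triage stroke as an emergency,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.3,Lack of appropriately trained staff to monitor tPA patients,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.4,Out of hour delays,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.5,Tasks performed sequentially rather than concurrently,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.6,Difficulties obtaining informed consent,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.7,No point of care testing in ED,EN|EDr|SN|SDr
3,All eligible patients receive rt-PA,3.8,tPA not stored in ED,EN|EDr|SN|SDr
4,Temperature taken on arrival,4.1,Lack of fever protocols,EN|EDr|SN|SDr
4,Temperature taken on arrival,4.2,Managing and organising busy nursing workload,EN|EDr|SN|SDr
4,Temperature taken on arrival,4.3,Belief that nurse clinical judgement should determine the frequency,EN|EDr|SN|SDr
4,Temperature taken on arrival,4.4,Longer the stay in ED the longer interval between assessment,EN|EDr|SN|SDr
4,Temperature taken on arrival,4.5,Higher triage category monitored less frequently,EN|EDr|SN|SDr
5,Treatment with paracetamol,5.1,Reluctance to administer paracetamol per rectum,EN|EDr|SN|SDr
5,Treatment with paracetamol,5.2,Concern administering paracetamol >= 37.5 C masks infection,EN|EDr|SN|SDr
5,Treatment with paracetamol,5.3,Intravenous paracetamol is not prescribed due to cost,EN|EDr|SN|SDr
5,Treatment with paracetamol,5.4,Local protocols restrict nurses to 1-2 doses of paracetamol,EN|EDr|SN|SDr
6,Finger prick BGL on admission,6.1,Enrolled nurses are not assessed to test BGL,EN|EDr|SN|SDr
6,Finger prick BGL on admission,6.2,Not enough BGL machines,EN|EDr|SN|SDr
7,Administration of insulin,7.1,Workforce issues nurse:patient ratio with insulin infusions,EN|EDr|SN|SDr
7,Administration of insulin,7.2,Lack of consensus treatment of hyperglycaemia in stroke,EN|EDr|SN|SDr
7,Administration of insulin,7.3,Lack of insulin dosage algorithms,EN|EDr|SN|SDr
7,Administration of insulin,7.4,EENs not able to adjust insulin,EN|EDr|SN|SDr
7,Administration of insulin,7.5,Patient requires nurse escort to tests if on insulin infusion,EN|EDr|SN|SDr
7,Administration of insulin,7.6,ED staff fear of hypoglycaemia,EN|EDr|SN|SDr
7,Administration of insulin,7.7,Not enough syringe drivers or pumps,EN|EDr|SN|SDr
8,NBM until a swallow screen,8.1,Doctors prescribing immediate aspirin when patient NBM,EN|SN|SP
8,NBM until a swallow screen,8.2,Doctors reluctance to use formal swallowing screen,EN|SN|SP
8,NBM until a swallow screen,8.3,Nurses administering aspirin before a swallow screen,EN|SN|SP
8,NBM until a swallow screen,8.4,Clinicians believing NBM does not include oral medications,EN|SN|SP
8,NBM until a swallow screen,8.5,Swallow screening will add to nurses' responsibilities in the ED,EN|SN|SP
8,NBM until a swallow screen,8.6,Speech pathology staff shortages delay in training nurses,EN|SN|SP
8,NBM until a swallow screen,8.7,Lack of communication,EN|SN|SP
8,NBM until a swallow screen,8.8,Lack of standardised swallow screening tools in ED,EN|SN|SP
9,Discharged to SU within 4 h,9.1,Unavailability of inpatient beds in stroke unit,EN|SN|BM
9,Discharged to SU within 4 h,9.2,Pressure to transfer out of ED means patients to general wards,EN|SN|BM
9,Discharged to SU within 4 h,9.3,Administrative procedures for transferring patients too long,EN|SN|BM
9,Discharged to SU within 4 h,9.4,Delay in obtaining a porter to transport patient from ED to SU,EN|SN|BM
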