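department,indication
endodontics clinic,endodontics
orthodontics clinic,orthodontic planning
pedodontics clinic,pedodontics
implantology clinic,implant placement
maxillofacial surgery,surgical planning and follow-up
oral radiology,second opinion radiodiagnosis
special dental care,medically compromised patient care
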