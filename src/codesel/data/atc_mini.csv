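code,parent,label
C,,Cardiovascular system
C07,C,Beta blocking agents
C07A,C07,Beta blocking agents
C07AB,C07A,"Beta blocking agents, selective"
C07AB02,C07AB,Metoprolol
C09,C,Agents acting on the renin-angiotensin system
C09A,C09,"ACE inhibitors, plain"
C09AA,C09A,"ACE inhibitors, plain"
C09AA05,C09AA,Ramipril
C10,C,Lipid modifying agents
C10A,C10,"Lipid modifying agents, plain"
C10AA,C10A,HMG CoA reductase inhibitors
C10AA05,C10AA,Atorvastatin
A,,Alimentary tract and metabolism
A10,A,Drugs used in diabetes
A10B,A10,"Blood glucose lowering drugs, excl. insulins"
A10BA,A10B,Biguanides
A10BA02,A10BA,Metformin
B,,Blood and blood forming organs
B01,B,Antithrombotic agents
B01A,B01,Antithrombotic agents
B01AC,B01A,Platelet aggregation inhibitors
B01AC06,B01AC,Acetylsalicylic acid
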