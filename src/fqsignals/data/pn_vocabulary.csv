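pt,soc,is_neuro,is_pn,category
Paraesthesia,Nervous system disorders,1,1,hyposensitivity
Hypoaesthesia,Nervous system disorders,1,1,hyposensitivity
Sensory loss,Nervous system disorders,1,1,hyposensitivity
Formication,Nervous system disorders,1,1,hyposensitivity
Loss of proprioception,Nervous system disorders,1,1,hyposensitivity
Burning sensation,Nervous system disorders,1,1,hypersensitivity
Hyperaesthesia,Nervous system disorders,1,1,hypersensitivity
Allodynia,Nervous system disorders,1,1,hypersensitivity
Electric shock sensation,Nervous system disorders,1,1,hypersensitivity
Neuralgia,Nervous system disorders,1,1,hypersensitivity
Neuropathic pain,Nervous system disorders,1,1,hypersensitivity
Burning feet syndrome,Nervous system disorders,1,1,hypersensitivity
Dysaesthesia,Nervous system disorders,1,1,hypersensitivity
Peripheral neuropathy,Nervous system disorders,1,1,unclassified_sensory
Sensory disturbance,Nervous system disorders,1,1,unclassified_sensory
Small fibre neuropathy,Nervous system disorders,1,1,unclassified_sensory
Axonal neuropathy,Nervous system disorders,1,1,unclassified_sensory
Peripheral sensory neuropathy,Nervous system disorders,1,1,unclassified_sensory
Polyneuropathy,Nervous system disorders,1,1,unclassified_sensory
Mononeuropathy,Nervous system disorders,1,1,unclassified_sensory
Toxic neuropathy,Nervous system disorders,1,1,unclassified_sensory
Demyelinating polyneuropathy,Nervous system disorders,1,1,unclassified_sensory
Chronic inflammatory demyelinating polyradiculoneuropathy,Nervous system disorders,1,1,unclassified_sensory
Neuritis,Nervous system disorders,1,1,unclassified_sensory
Autonomic neuropathy,Nervous system disorders,1,1,unclassified_sensory
Areflexia,Nervous system disorders,1,1,unclassified_sensory
Peripheral motor neuropathy,Nervous system disorders,1,1,motor
Peripheral sensorimotor neuropathy,Nervous system disorders,1,1,motor
Dizziness,Nervous system disorders,1,0,none
Headache,Nervous system disorders,1,0,none
Tremor,Nervous system disorders,1,0,none
Somnolence,Nervous system disorders,1,0,none
Seizure,Nervous system disorders,1,0,none
Syncope,Nervous system disorders,1,0,none
Migraine,Nervous system disorders,1,0,none
Dysgeusia,Nervous system disorders,1,0,none
Tendonitis,Musculoskeletal and connective tissue disorders,0,0,none
Tendon rupture,Musculoskeletal and connective tissue disorders,0,0,none
Arthralgia,Musculoskeletal and connective tissue disorders,0,0,none
Myalgia,Musculoskeletal and connective tissue disorders,0,0,none
Pain in extremity,Musculoskeletal and connective tissue disorders,0,0,none
Muscular weakness,Musculoskeletal and connective tissue disorders,0,0,none
Fatigue,General disorders and administration site conditions,0,0,none
Asthenia,General disorders and administration site conditions,0,0,none
Pain,General disorders and administration site conditions,0,0,none
Drug ineffective,General disorders and administration site conditions,0,0,none
Multiple organ dysfunction syndrome,General disorders and administration site conditions,0,0,none
Insomnia,Psychiatric disorders,0,0,none
Anxiety,Psychiatric disorders,0,0,none
Depression,Psychiatric disorders,0,0,none
Nausea,Gastrointestinal disorders,0,0,none
Diarrhoea,Gastrointestinal disorders,0,0,none
Vomiting,Gastrointestinal disorders,0,0,none
Rash,Skin and subcutaneous tissue disorders,0,0,none
Toxic epidermal necrolysis,Skin and subcutaneous tissue disorders,0,0,none
Tinnitus,Ear and labyrinth disorders,0,0,none
Visual impairment,Eye disorders,0,0,none
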