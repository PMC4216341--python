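ailment,category
Abdominal pain,Gastrointestinal disorders
Arm pain,Pains
Arthritis,Muscular-skeletal disorders
Bone diseases,Muscular-skeletal disorders
Cancer,Others
Carpal tunnel syndrome,Muscular-skeletal disorders
Cattle disease,Veterinary ailments
Chronic myofascial pain,Muscular-skeletal disorders
Common cold,Respiratory system disorders
Convulsion,Nervous system disorders
Cough,Respiratory system disorders
Edema,Circulatory system disorders
Eye disease,Others
Fatigue,Others
Finger pain,Pains
Gastric ulcer,Gastrointestinal disorders
Gastritis,Gastrointestinal disorders
Gastroenteric disorder,Gastrointestinal disorders
Glycosuria,Diabetes
Hemorrhaging,Cuts and wounds
Hookworm,Others
Hyperthermia,Others
Hypofunction,Others
Indigestion,Gastrointestinal disorders
Jaundice,Liver complaints
Knee pain,Pains
Lacquer poisoning,Poisonings
Leg pain,Pains
Liver diseases,Liver complaints
Lumbago,Muscular-skeletal disorders
Paralysis,Nervous system disorders
Pig disease,Veterinary ailments
Pollakiuria,Genitourinary system disorders
Pruritus,Skin diseases and disorders
Pus,Inflammation
Raynaud's Phenomenon,Circulatory system disorders
Sexual enhancement,Genitourinary system disorders
Shoulder pain,Pains
Sinews and joint pain,Muscular-skeletal disorders
Skin diseases,Skin diseases and disorders
Snakebite,Poisonings
Sterility,Birth-related disorders
Woman diseases,Birth-related disorders
Wound,Cuts and wounds
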