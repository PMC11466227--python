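code,description,group
C91,Lymphoid leukaemia,cancer/blood
D56,Thalassaemia,cancer/blood
D61,Aplastic anaemia,cancer/blood
D66,Hereditary factor VIII deficiency,cancer/blood
Q210,Ventricular septal defect,cardiovascular
Q250,Patent ductus arteriosus,cardiovascular
I42,Cardiomyopathy,cardiovascular
Q234,Hypoplastic left heart syndrome,cardiovascular
J45,Asthma,respiratory
J47,Bronchiectasis,respiratory
E84,Cystic fibrosis,respiratory
P27,Chronic respiratory disease originating in the perinatal period,respiratory
G40,Epilepsy,neurological
G80,Cerebral palsy,neurological
Q05,Spina bifida,neurological
G712,Congenital myopathies,neurological
F84,Pervasive developmental disorders,mental health/behavioural
F90,Hyperkinetic disorders,mental health/behavioural
F32,Depressive episode,mental health/behavioural
F50,Eating disorders,mental health/behavioural
K529,Noninfective gastroenteritis and colitis unspecified,metabolic and other
E10,Type 1 diabetes mellitus,metabolic and other
N18,Chronic kidney disease,metabolic and other
K50,Crohn disease,metabolic and other
E700,Classical phenylketonuria,metabolic and other
Q614,Renal dysplasia,metabolic and other
M08,Juvenile arthritis,musculoskeletal/skin
M41,Scoliosis,musculoskeletal/skin
L40,Psoriasis,musculoskeletal/skin
Q792,Exomphalos,musculoskeletal/skin
B20,Human immunodeficiency virus disease,chronic infections
B181,Chronic viral hepatitis B,chronic infections
Z93,Artificial opening status,non-specific
R62,Lack of expected normal physiological development,non-specific
Z991,Dependence on respirator,non-specific
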