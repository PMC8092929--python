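# Disease / condition lexicon for synthetic family-history notes and
# dictionary tagging.  One entry per line; includes nested multiword
# names (e.g. diabetes / diabetes type 2) to exercise partial matching,
# plus mental-health and substance-related conditions.
diabetes
diabetes type 1
diabetes type 2
gestational diabetes
hypertension
high blood pressure
high cholesterol
hyperlipidemia
heart disease
congenital heart disease
coronary artery disease
heart failure
congestive heart failure
atrial fibrillation
heart murmur
cardiomyopathy
myocardial infarction
angina
stroke
transient ischemic attack
aneurysm
peripheral vascular disease
deep vein thrombosis
pulmonary embolism
blood clots
anemia
sickle cell anemia
sickle cell trait
hemophilia
thalassemia
leukemia
lymphoma
hodgkin lymphoma
multiple myeloma
cancer
breast cancer
ovarian cancer
cervical cancer
uterine cancer
endometrial cancer
prostate cancer
testicular cancer
colon cancer
colorectal cancer
stomach cancer
gastric cancer
pancreatic cancer
liver cancer
lung cancer
skin cancer
melanoma
basal cell carcinoma
bladder cancer
kidney cancer
thyroid cancer
brain cancer
brain tumor
bone cancer
esophageal cancer
throat cancer
asthma
chronic obstructive pulmonary disease
emphysema
chronic bronchitis
cystic fibrosis
pulmonary fibrosis
sleep apnea
tuberculosis
pneumonia
arthritis
rheumatoid arthritis
osteoarthritis
psoriatic arthritis
gout
lupus
systemic lupus erythematosus
fibromyalgia
osteoporosis
scoliosis
muscular dystrophy
multiple sclerosis
amyotrophic lateral sclerosis
parkinson disease
alzheimer disease
dementia
vascular dementia
epilepsy
seizures
seizure disorder
migraines
chronic headaches
neuropathy
peripheral neuropathy
cerebral palsy
spina bifida
hydrocephalus
hydrocephaly
huntington disease
tourette syndrome
restless leg syndrome
narcolepsy
insomnia
depression
untreated depression
postpartum depression
major depressive disorder
anxiety
generalized anxiety disorder
panic disorder
panic attacks
bipolar disorder
schizophrenia
schizoaffective disorder
obsessive compulsive disorder
post traumatic stress disorder
attention deficit hyperactivity disorder
adhd
autism
autism spectrum disorder
eating disorder
anorexia
bulimia
alcoholism
alcohol abuse
alcohol dependence
substance abuse
drug addiction
opioid dependence
nicotine dependence
gambling addiction
thyroid disease
hypothyroidism
hyperthyroidism
graves disease
hashimoto thyroiditis
goiter
addison disease
cushing syndrome
polycystic ovary syndrome
endometriosis
infertility
miscarriages
multiple miscarriages
preeclampsia
kidney disease
chronic kidney disease
polycystic kidney disease
kidney stones
kidney failure
nephritis
liver disease
cirrhosis
fatty liver disease
hepatitis
hepatitis b
hepatitis c
gallstones
gallbladder disease
pancreatitis
celiac disease
crohn disease
ulcerative colitis
irritable bowel syndrome
diverticulitis
acid reflux
gastroesophageal reflux disease
peptic ulcers
stomach ulcers
obesity
morbid obesity
metabolic syndrome
gestational hypertension
glaucoma
macular degeneration
cataracts
retinitis pigmentosa
color blindness
hearing loss
congenital deafness
meniere disease
eczema
psoriasis
vitiligo
rosacea
severe allergies
food allergies
hay fever
hives
immune deficiency
hiv
human immunodeficiency virus
rheumatic fever
scarlet fever
meningitis
encephalitis
polio
shingles
mononucleosis
lyme disease
malaria
down syndrome
turner syndrome
klinefelter syndrome
fragile x syndrome
marfan syndrome
ehlers danlos syndrome
neurofibromatosis
phenylketonuria
tay sachs disease
gaucher disease
wilson disease
hemochromatosis
familial hypercholesterolemia
birth defects
cleft palate
cleft lip
clubfoot
congenital hip dysplasia
mental retardation
developmental delay
learning disabilities
dyslexia
speech delay
failure to thrive
premature birth
neonatal death
sudden infant death syndrome
genetic conditions
chromosomal abnormalities
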