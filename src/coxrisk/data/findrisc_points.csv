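# Finnish Diabetes Risk Score (FINDRISC) point table, full 8-item version
# (score range 0-26; validated high-risk thresholds fall in 11-14 points).
# Citation: Lindstrom J, Tuomilehto J. The Diabetes Risk Score: a practical
# tool to predict type 2 diabetes risk. Diabetes Care 2003;26:725-731.
# Numeric categories use the convention lower <= value < upper (blank bound
# = unbounded); ages in years, BMI in kg/m^2, waist circumference in cm.
# kind=numeric rows carry lower/upper; kind=boolean rows score `points` when
# the item is positive (physical_activity scores when NEGATIVE, i.e. fewer
# than 30 minutes of daily activity); kind=family rows score by closest
# affected relative degree.
item,kind,sex,lower,upper,value,points
age,numeric,any,,45,,0
age,numeric,any,45,55,,2
age,numeric,any,55,65,,3
age,numeric,any,65,,,4
bmi,numeric,any,,25,,0
bmi,numeric,any,25,30,,1
bmi,numeric,any,30,,,3
waist_cm,numeric,male,,94,,0
waist_cm,numeric,male,94,102,,3
waist_cm,numeric,male,102,,,4
waist_cm,numeric,female,,80,,0
waist_cm,numeric,female,80,88,,3
waist_cm,numeric,female,88,,,4
physical_activity,boolean,any,,,negative,2
vegetables_daily,boolean,any,,,negative,1
bp_medication,boolean,any,,,positive,2
high_glucose_history,boolean,any,,,positive,5
family_history,family,any,,,first_degree,5
family_history,family,any,,,second_degree,3
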