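term	canonical_symptom	category	subcategory	nocturnal_only
tremor	tremor	motor	tremor	0
trembling	tremor	motor	tremor	0
stiffness	stiffness	motor	rigidity	0
rigidity	stiffness	motor	rigidity	0
difficulty turning over	turning_over	motor	rigidity	0
immobility	immobility	motor	rigidity	0
difficulty walking	difficulty_walking	motor	bradykinesia	0
slow movement	difficulty_walking	motor	bradykinesia	0
reduced facial expression	reduced_facial_expression	motor	bradykinesia	0
unclear enunciation	unclear_enunciation	motor	bradykinesia	0
speech disorder	speech_disorder	motor	bradykinesia	0
falling	falling	motor	postural_instability	0
gait instability	gait_instability	motor	postural_instability	0
pain	pain	non_motor	sleep_sensory	0
aching	pain	non_motor	sleep_sensory	0
frequent urination	frequent_urination	non_motor	sleep_sensory	0
insomnia	insomnia	non_motor	sleep_sensory	1
rbd	rbd	non_motor	sleep_sensory	1
dream enactment	rbd	non_motor	sleep_sensory	1
poor sleep quality	poor_sleep_quality	non_motor	sleep_sensory	1
fragmented sleep	fragmented_sleep	non_motor	sleep_sensory	1
daytime sleepiness	daytime_sleepiness	non_motor	sleep_sensory	1
numbness	numbness	non_motor	sleep_sensory	0
spasm	spasm	non_motor	sleep_sensory	0
cramping	spasm	non_motor	sleep_sensory	0
olfactory disorder	olfactory_disorder	non_motor	sleep_sensory	0
restless legs	restless_legs	non_motor	sleep_sensory	0
difficulty breathing	difficulty_breathing	non_motor	sleep_sensory	0
depression	depression	non_motor	cognitive_psychiatric	0
anxiety	anxiety	non_motor	cognitive_psychiatric	0
hallucinations	hallucinations	non_motor	cognitive_psychiatric	0
dementia	dementia	non_motor	cognitive_psychiatric	0
slow reaction	slow_reaction	non_motor	cognitive_psychiatric	0
apathy	apathy	non_motor	cognitive_psychiatric	0
psychiatric issues	psychiatric_other	non_motor	cognitive_psychiatric	0
constipation	constipation	non_motor	autonomic	0
gastrointestinal discomfort	gastrointestinal	non_motor	autonomic	0
drooling	drooling	non_motor	autonomic	0
nocturia	nocturia	non_motor	autonomic	1
dyskinesia	dyskinesia	motor_complication	dyskinesia	0
involuntary movements	dyskinesia	motor_complication	dyskinesia	0
motor fluctuation	motor_fluctuation	motor_complication	motor_fluctuation	0
wearing off	motor_fluctuation	motor_complication	motor_fluctuation	0
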