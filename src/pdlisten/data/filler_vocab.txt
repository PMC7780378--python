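hello
doctor
father
mother
years
since
diagnosed
taking
levodopa
tablets
every
evening
recently
getting
worse
please
advise
thank
appreciate
visited
hospital
clinic
prescribed
medication
dosage
adjust
whether
should
continue
together
family
care
daily
routine
exercise
outside
because
sometimes
often
really
trouble
describe
started
month
weekly
condition
progress
question
answer
suggest
examination
checkup
report
result
normal
review
follow
consult
online
platform
grateful
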