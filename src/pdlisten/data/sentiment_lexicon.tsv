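term	grade	label
doubtful	1	suspicion
unconvinced	1	suspicion
skeptical	1	suspicion
worried	2	anxiety
anxious	2	anxiety
restlessness	2	anxiety
afraid	3	fear
scared	3	fear
terrified	3	fear
suffering	4	agony
agonizing	4	agony
tormented	4	agony
angry	5	anger
furious	5	anger
resentful	5	anger
sorrowful	6	sorrow
grieving	6	sorrow
hopeless	6	sorrow
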