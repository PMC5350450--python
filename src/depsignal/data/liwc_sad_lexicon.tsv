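# Depression-related keyword lexicon (110 entries).
# Columns: block_label <TAB> pattern.  A trailing "*" marks a prefix wildcard.
# Blocks: the symptom/stressor category a keyword was curated for, or
# "liwc_sad" for the LIWC "sad" category keyword list.
# The pattern "divorc" is preserved verbatim (no wildcard) as printed.
depressed_mood	pain
weight_change	appetite
disturbed_sleep	insomnia
psychomotor_agitation	restless
psychomotor_agitation	jitter*
psychomotor_agitation	groggy
psychomotor_agitation	dazed
fatigue	tired
worthlessness	guilt*
worthlessness	burden
diminished_concentration	concentrat*
diminished_concentration	focus*
diminished_concentration	indeci*
suicidal_ideation	suicid*
suicidal_ideation	kill
primary_support	death
primary_support	die*
primary_support	funeral
primary_support	cremat*
primary_support	divorc
primary_support	abus*
primary_support	neglect*
occupational_problems	fired
occupational_problems	unemploy*
housing_problems	homeless*
liwc_sad	abandon*
liwc_sad	ache*
liwc_sad	aching
liwc_sad	agoni*
liwc_sad	alone
liwc_sad	broke*
liwc_sad	cried
liwc_sad	cries
liwc_sad	crushed
liwc_sad	cry
liwc_sad	damag*
liwc_sad	defeat*
liwc_sad	depress*
liwc_sad	depriv*
liwc_sad	despair*
liwc_sad	devastat*
liwc_sad	disadvantage*
liwc_sad	disappoint*
liwc_sad	discourag*
liwc_sad	dishearten*
liwc_sad	disillusion*
liwc_sad	dissatisf*
liwc_sad	doom*
liwc_sad	dull*
liwc_sad	empt*
liwc_sad	fail*
liwc_sad	fatigu*
liwc_sad	flunk*
liwc_sad	gloom*
liwc_sad	grave*
liwc_sad	grief
liwc_sad	griev*
liwc_sad	grim*
liwc_sad	heartbr*
liwc_sad	helpless*
liwc_sad	homesick*
liwc_sad	hopeless*
liwc_sad	hurt*
liwc_sad	inadequa*
liwc_sad	inferior*
liwc_sad	isolat*
liwc_sad	lame*
liwc_sad	lone*
liwc_sad	longing*
liwc_sad	lose
liwc_sad	loser*
liwc_sad	loses
liwc_sad	losing
liwc_sad	loss*
liwc_sad	lost
liwc_sad	melanchol*
liwc_sad	miser*
liwc_sad	mourn*
liwc_sad	neglect*
liwc_sad	overwhelm*
liwc_sad	pathetic*
liwc_sad	pessimis*
liwc_sad	piti*
liwc_sad	pity*
liwc_sad	regret*
liwc_sad	reject*
liwc_sad	remorse*
liwc_sad	resign*
liwc_sad	ruin*
liwc_sad	sad
liwc_sad	sobbed
liwc_sad	sobbing
liwc_sad	sobs
liwc_sad	solemn*
liwc_sad	sorrow*
liwc_sad	suffer*
liwc_sad	tears*
liwc_sad	traged*
liwc_sad	tragic*
liwc_sad	unhapp*
liwc_sad	unimportant
liwc_sad	unsuccessful*
liwc_sad	useless*
liwc_sad	weep*
liwc_sad	wept
liwc_sad	whine*
liwc_sad	whining
liwc_sad	woe*
liwc_sad	worthless*
liwc_sad	yearn*
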