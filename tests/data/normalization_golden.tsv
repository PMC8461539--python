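raw	normalized
Can't stop HPV-vaccine lies & myths	cannot stop hpv vaccine lies and myths
@a @b @c gardasil	MENTION MENTION gardasil
RT @user: Gardasil causes 2x the pain!! https://t.co/xyz	RT MENTION gardasil causes NUMBER x the pain
You'll regret it... #truth #vaccineinjury	you will regret it truth vaccineinjury
HPV shot prevents 90% of cervical cancers http://cdc.gov/hpv	hpv shot prevents NUMBER of cervical cancers
my daughter got her 2nd dose w/o issues	my daughter got her NUMBER nd dose without issues
DON'T LET THEM WIN	do not let them win
vaccines/autism link DEBUNKED	vaccines autism link debunked
she's fine now - thankfully	she is fine now thankfully
RT @news: study of 1,000,000 girls finds no risk	RT MENTION study of NUMBER girls finds no risk
it's not worth it	it is not worth it
@doc @nurse @mom @dad please read this	MENTION MENTION please read this
I've read 3 studies... none convincing	i have read NUMBER studies none convincing
#Gardasil9 works	gardasil NUMBER works
won't somebody think of the children?!	will not somebody think of the children
HPV16/18 strains covered	hpv NUMBER NUMBER strains covered
due to the vaccine, she developed POTS	due to the vaccine she developed pots
they're hiding the truth & the data	they are hiding the truth and the data
100% safe? doubt it	NUMBER safe doubt it
who's paying for these 'studies'	who is paying for these studies
w/ 2 doses you're protected	with NUMBER doses you are protected
RT RT RT fake news	RT RT RT fake news
rt @user2: banned in Japan!!!	RT MENTION banned in japan
weren't we promised transparency	were not we promised transparency
CERVICAL CANCER IS PREVENTABLE	cervical cancer is preventable
3-in-1 shot available now	NUMBER in NUMBER shot available now
read this thread 1/12	read this thread NUMBER NUMBER
that's that.	that is that
   leading   spaces   and   trailing   	leading spaces and trailing
✨ gardasil ✨ killed ✨ my ✨ daughter ✨	gardasil killed my daughter
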