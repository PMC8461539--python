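phrase,category
premature ovarian failure,category_0_gardasil
premature ovarian,category_0_gardasil
premature ovarian failure extreme,category_0_gardasil
premature related0,category_0_gardasil
early onset menopause,category_1_hpvvaccine
early onset,category_1_hpvvaccine
early onset menopause extreme,category_1_hpvvaccine
early related1,category_1_hpvvaccine
chronic pain,category_2_hpvshot
chronic,category_2_hpvshot
chronic pain extreme,category_2_hpvshot
chronic related2,category_2_hpvshot
sudden paralysis,category_3_cervarix
sudden,category_3_cervarix
sudden paralysis extreme,category_3_cervarix
sudden related3,category_3_cervarix
lasting allergy,category_4_silgard
lasting,category_4_silgard
lasting allergy extreme,category_4_silgard
lasting related4,category_4_silgard
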