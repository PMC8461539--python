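# Default causal-cue lexicon: a user-replaceable stand-in list of lexical
# markers of cause->effect assertions in informal short text.
# One cue per line; multi-word cues allowed; '#' lines are comments.
cause
causes
caused
causing
lead to
leads to
led to
result in
results in
resulted in
due to
because of
linked to
trigger
triggers
triggered
prevent
prevents
prevented
because
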