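# Known chain base names, one per line: these group on the exact base
# name during deduplication whether or not a location suffix is present.
mcdonald's
burger king
kfc
pizza hut
papa john's
domino's
subway
greggs
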