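# Negation triggers, one per line. Multi-word triggers are matched
# before single-word ones. A trigger opens a removal scope that runs
# to the next sentence terminator (. ; :) or scope-breaking
# conjunction (but / however / although).
negative for
free of
rather than
ruled out
no
not
without
denies
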