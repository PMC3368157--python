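# Tokens (lowercased, period included) that do NOT end a sentence.
# Single capital letters followed by a period ("E.", "S.") are handled
# by rule and need not be listed.
al.
approx.
ca.
cf.
dr.
e.g.
eq.
et al.
etc.
fig.
figs.
i.e.
inc.
no.
ref.
refs.
sp.
spp.
st.
viz.
vs.
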