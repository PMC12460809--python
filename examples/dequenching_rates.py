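"""Estimate relative disassembly activity from dequenching traces.

Fluorescence dequenching reports SNARE-complex disassembly; the slope of
the linear phase (95-350 s) is the rate. Here a mutant enzyme is generated
at 28% of the wild-type rate and the ratio is recovered by linear
regression with propagated uncertainty.
"""

from ringscape import disassembly_rate, generate_trace, rate_ratio

wild_type = generate_trace(slope=1.0, noise=0.5, seed=0)
mutant = generate_trace(slope=0.28, noise=0.5, seed=1)

wt = disassembly_rate(wild_type)
mut = disassembly_rate(mutant)
ratio, err = rate_ratio(mut, wt)

print(f"wild-type slope: {wt[0]:.4f} +- {wt[1]:.4f} signal/s")
print(f"mutant slope:    {mut[0]:.4f} +- {mut[1]:.4f} signal/s")
print(f"relative rate:   {100 * ratio:.1f} +- {100 * err:.1f} %")
# The mutant disassembles at ~28% of the wild-type rate, matching the
# planted ratio within the regression uncertainty.
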