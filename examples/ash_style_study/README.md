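# ash_style_study

A small synthetic study generated by `epochdec simulate --seed 11 --n-extant 20`:
a 27-tip chronogram (20 extant + 7 fossil tips, root 53.9 Ma) with tip ranges
forward-simulated under DEC (d = 0.015, e = 0.005) on the six-region,
three-epoch connectivity schedule, a noisy Cenozoic-style temperature series,
and the full ground truth (true tree, node/corner states, branch paths, event
log) alongside the analysis inputs.

Run the whole analysis with:

    epochdec run --config examples/ash_style_study/config.yaml --out out/

or extract events straight from the ground truth:

    epochdec events --true-history examples/ash_style_study --out out/
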