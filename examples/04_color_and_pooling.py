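"""CIELAB color change and pooling of clinical-trial effectiveness.

Computes ΔE*ab from before/after L*a*b* coordinates, classifies changes against
the 1.2 (perceptibility) and 2.7 (acceptability) thresholds, and pools the
packaged randomized-trial arms into per-strategy effectiveness estimates.
"""

from dentcea import (
    LabColor,
    classify_color_change,
    delta_e_ab,
    load_included_trials,
    pool_effectiveness,
)

before = LabColor(L=68.0, a=2.5, b=21.0)
after = LabColor(L=74.5, a=1.2, b=14.0)  # lighter and less yellow after bleaching
de = delta_e_ab(before, after)
print(f"ΔE*ab = {de:.2f} -> {classify_color_change(de).value}")
print()

arms = load_included_trials()
print("Pooled effectiveness per strategy (sample-size-weighted mean over arms):")
for name in ("CD", "BCD", "HPD", "CP10"):
    strategy_arms = [a for a in arms if a.strategy_name == name]
    mean, _ = pool_effectiveness(strategy_arms)
    label = classify_color_change(mean).value
    total_n = sum(a.n for a in strategy_arms)
    print(f"  {name:>4}: ΔE*ab = {mean:.2f} over {len(strategy_arms)} arm(s), n = {total_n:>3} -> {label}")
print()
print(
    "Only changes above 2.7 ΔE*ab count as clinically acceptable whitening; the\n"
    "dentifrice controls sit near the 1.2 perceptibility limit, the peroxide\n"
    "dentifrice clears it, and at-home bleaching is far above both thresholds."
)
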