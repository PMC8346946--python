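"""Reading-order half differentials on a synthetic corpus.

Generates a corpus whose strokes fall in the first-read half of each
character 60% of the time, splits every glyph into left/right halves,
and fits the order-model suite.  A positive first-minus-last intercept
means the half read first carries more visual complexity; a negative
directionality coefficient in the left-minus-right model is the mirror of
the same effect in right-to-left scripts.
"""

from glyphcomplexity import GeneratorSpec, build_half_table, generate_corpus
from glyphcomplexity.stats import order_models

spec = GeneratorSpec(
    n_families=4, scripts_per_family=5, chars_per_script=10,
    first_half_share=0.60, seed=2,
)
bundle = generate_corpus(spec)
table = build_half_table(bundle.glyphs, bundle.inventory)
print(f"{len(bundle.glyphs)} glyphs -> {len(table)} measured halves")

suite = order_models(table, metrics=("ac",))
fit = suite["ac"]["first_last_intercept"]
print("\nfirst-minus-last AC differential (intercept-only mixed model):")
print(fit.summary().round(3).to_string())

if "left_right_direction" in suite["ac"]:
    d = suite["ac"]["left_right_direction"]
    print("\nleft-minus-right AC ~ directionality(RL):")
    print(d.summary().round(3).to_string())

print("\nΔAIC order-vs-side model:", round(suite["ac"]["order_vs_side_daic"], 1),
      "(positive: reading order explains half complexity better than physical side)")
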