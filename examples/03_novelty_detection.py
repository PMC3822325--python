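"""Novelty detection with the uniform unknown-symbol model.

Trains on only three shapes.  Every likelihood term conditioned on the
unknown symbol "$" is uniform, so "$" wins exactly when the trace fits no
trained shape better than chance.  The decision is taken before auxiliary
variables: letter sizes vary little across an alphabet and would mask
novelty.
"""

from eyewrite import (
    GeneratorConfig,
    ModelConfig,
    curated_templates,
    featurize_database,
    generate_database,
    is_novel,
    learn_model,
    novelty_posterior,
)

known = ["loop", "zigzag", "arc"]
db = featurize_database(
    generate_database(known + ["spiral", "vee"], 9, GeneratorConfig(), seed=5)
)
model = learn_model([e for e in db if e.label in known], ModelConfig.for_symbols(known))

for label in ("loop", "spiral", "vee"):
    ex = next(e for e in db if e.label == label)
    post = novelty_posterior(model, ex.via_points)
    verdict = "NEW symbol" if is_novel(post) else f"known {post.argmax!r}"
    print(f"presented {label!r:9s}: P($) = {post['$']:.3f} -> {verdict}")
print("Trained shapes are claimed by their own symbol; unseen shapes fall to '$'.")
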