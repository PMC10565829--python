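"""Generate a small annotated dataset of artificial reaction schemes.

Composes linear 2-step schemes (diagram glyphs, solid arrows, labels,
conditions text, plus-sign decoys) on a blank canvas and writes PNGs, a
COCO-dialect annotation file and per-scheme ground-truth graphs.
"""

from rxnscheme import SchemaSpec, generate_dataset

schema = SchemaSpec(
    layout="linear",
    n_steps=2,                 # reaction steps per scheme
    diagrams_per_step=(1, 2),  # 1-2 species per reactant/product group
    p_label=0.6,               # chance a diagram gets a chemical label
    p_conditions=0.6,          # chance an arrow gets a conditions block
    n_negatives=(0, 2),        # decoy symbols per scheme
)

manifest = generate_dataset(n=5, schema=schema, seed=7, outdir="scratch/demo_dataset")

print(f"wrote {manifest['n']} schemes to scratch/demo_dataset/")
for entry in manifest["schemes"]:
    print(f"  {entry['image']}  (ground truth: {entry['graph']}, seed {entry['seed']})")
# Each PNG is one scheme; annotations.json holds every region box with its
# class (diagram/label/conditions/arrow); the per-scheme JSON adds the
# label->diagram and conditions->arrow pairings and the reaction graph.
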