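"""Generate a small synthetic hexaploid dataset with planted truth.

Builds a 21-chromosome genome carrying a transcription-factor family
organized into triad groups, tandem clusters, two-subgenome pairs and
orphans, then prints what was planted.  The same seed always produces
byte-identical files.
"""

from homeobias import SynthConfig, generate_dataset

cfg = SynthConfig(seed=1, n_groups=10, n_clusters=2, n_pairs=2, n_orphans=3,
                  n_background=5, chromosome_length=150_000)
bundle = generate_dataset(cfg, "example_out/bundle")

truth = bundle.truth
print("files:", sorted(p.name for p in bundle.outdir.iterdir()))
print("planted components:")
print(truth.components["class"].value_counts().to_string())
fam = truth.genes["is_family"].sum()
print(f"{len(truth.genes)} genes total, {fam} family members, "
      f"{len(truth.genes) - fam} background genes")
# Each 'group' row is a complete homeolog triad: one copy per subgenome
# (A, B, D) on the same chromosome number, e.g. 3A/3B/3D.
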