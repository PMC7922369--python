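"""End-to-end run: synthetic bundle in, stage tables out.

Generates the default study-scale bundle (60 groups, 5 clusters, 4
pairs, 10 orphans), runs every stage, and scores recovery against the
planted truth.
"""

from pathlib import Path

from homeobias import (
    PipelineConfig,
    SynthConfig,
    generate_dataset,
    run_pipeline,
    score_component_recovery,
    score_bias_recovery,
)
from homeobias.evaluate import bias_calls_from_tables

bundle = generate_dataset(SynthConfig(seed=1), "example_out/bundle_full")
cfg = PipelineConfig(
    protein_fasta=str(bundle.protein_fasta),
    gff3=str(bundle.gff3),
    genome_fasta=str(bundle.genome_fasta),
    vcf=str(bundle.vcf),
    fpkm_tsv=str(bundle.fpkm_tsv),
    design_tsv=str(bundle.design_tsv),
    outdir="example_out/run_full",
    seed=1,
)
report = run_pipeline(cfg)
print("stage counts:", report.stage_counts)

out = Path(cfg.outdir)
comps, calls = bias_calls_from_tables(out / "components.tsv", out / "bias.tsv")
print("component classification accuracy:",
      score_component_recovery(bundle.truth, comps))
print("sub/neo bias label recovery:",
      score_bias_recovery(bundle.truth, calls, comps, labels=("sub", "neo")))
# Both scores are 1.0 at the default planted effect size: every planted
# triad/cluster/pair/orphan is rebuilt from sequence alone and every
# planted sub-/neo-functionalization verdict is reproduced.
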