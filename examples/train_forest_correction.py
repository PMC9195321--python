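"""Train the per-base random-forest correctors and apply them held-out.

The forests are trained on one simulated genome (with planted inexact
repeats, which produce the ambiguous low-quality alignments the anchor
classifier is for) and evaluated on reads from a different genome, so the
classifier never sees the evaluation genome (leave-one-genome-out).  Forest
mode should keep false positives at or below the rule-based mode while
correcting a comparable number of errors.
"""

import msacorrect as mc
from msacorrect.forest import TrainingDataset, train_forests

pipeline = mc.PipelineConfig(coverage=30, paired=True)

train_cfg = mc.SimulationConfig(genome_length=6_000, coverage=30, seed=1,
                                repeat_spec=(8, 300, 0.03))
train_genome = mc.simulate_genome(train_cfg)
train_reads, train_perfect, _ = mc.simulate_reads(train_genome, train_cfg)
anchor_model, cand_model = train_forests(
    [TrainingDataset(train_reads, train_perfect, "genomeA")], pipeline, seed=0
)
print("anchor forest:", anchor_model.metadata)

eval_cfg = mc.SimulationConfig(genome_length=5_000, coverage=30, seed=2)
genome = mc.simulate_genome(eval_cfg)
reads, perfect, _ = mc.simulate_reads(genome, eval_cfg)

for mode, models in (("classic", (None, None)),
                     ("forest", (anchor_model, cand_model))):
    cfg = mc.PipelineConfig(coverage=30, paired=True, mode=mode)
    res = mc.run_correction(reads, cfg, *models)
    c = mc.compare_three_way(reads, perfect, res.corrected_reads)
    print(f"{mode:8s} TP={c.TP:5d} FP={c.FP:3d} FN={c.FN:4d}")
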