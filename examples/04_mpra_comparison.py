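"""Compare VIP predictions with a simulated reporter assay.

Builds a reporter construct carrying one class's motifs, draws an SNV panel,
simulates per-class expression changes (signal for classes whose motifs are
planted, pure noise otherwise) and correlates VIP with expression change per
class.  The expressing class should show a clear positive correlation, the
non-expressing class none — the signature of models being predictive only in
cell types where the element is active.
"""

import tempfile
from pathlib import Path

import pandas as pd

from crevip import pearson_correlation
from crevip.io import VariantRecord
from crevip.pipeline import (PipelineConfig, run_prepare, run_simulate,
                             run_train_and_evaluate)
from crevip.simulate import (construct_variant_panel, make_reporter_construct,
                             simulate_genome_and_peaks, simulate_mpra)
from crevip.variants import delta_svm_snv

cfg = PipelineConfig(word_length=6, k=4, n_classes=3, peaks_per_class=60,
                     region_width=61, genome_length=120_000, flank=30, seed=7)
_, _, truth = simulate_genome_and_peaks(cfg.synthetic_spec())

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    sim_cfg = run_simulate(cfg, tmp / "sim")
    prepared = run_prepare(sim_cfg, tmp / "prep")
    trained = run_train_and_evaluate(sim_cfg, tmp / "train", prepared)

construct, sites = make_reporter_construct(truth, "class0", seed=100)
panel = construct_variant_panel(construct, sites, n_in_motif=45,
                                n_background=105, seed=101)
variants = [VariantRecord(r.id, "construct", int(r.pos), r.ref, r.alt)
            for r in panel.itertuples(index=False)]
records = simulate_mpra(construct, variants, truth, seed=102)

vip = [delta_svm_snv(trained["weights"]["class0"], construct, int(p), a)
       for p, a in zip(panel.pos, panel.alt)]
frame = pd.DataFrame([{"id": r.variant_id, "cell_class": r.cell_class,
                       "change": r.expression_change} for r in records])
print("Pearson r of class0-model VIP vs expression change, by cell class:")
for cell_class, group in frame.groupby("cell_class"):
    change = group.set_index("id").loc[panel.id, "change"]
    r = pearson_correlation(vip, change.to_numpy())
    note = "(expressing)" if cell_class == "class0" else ""
    print(f"  {cell_class}: r = {r:+.3f} {note}")
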