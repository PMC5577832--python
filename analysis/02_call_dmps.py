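#!/usr/bin/env python
"""Call single-probe DMPs on the synthetic scene.

Per-probe two-group ANOVA at non-adjusted p < 0.001, direction and
effect-size summary at the 0.15 threshold, volcano table and sample PCA.
Writes dmps.tsv / volcano.tsv / pca.tsv / dmp_summary.json under
results/ and reports how many spiked probes were recovered.
"""

import json
from pathlib import Path

from wsmeth.array_io import read_beta_matrix, read_manifest, write_table
from wsmeth.dmp import call_dmps, dmps_to_frame, sample_pca, summarize_dmps, volcano_table

BASE = Path(__file__).resolve().parent.parent / "results"
FIX = BASE / "synthetic"


def main() -> None:
    annotations = {a.probe_id: a for a in read_manifest(FIX / "manifest.tsv")}
    matrix = read_beta_matrix(FIX / "betas.tsv", FIX / "samples.tsv")
    dmps = call_dmps(matrix, annotations, p_threshold=0.001)
    summary = summarize_dmps(dmps, p_threshold=0.001, effect_threshold=0.15)

    write_table(dmps_to_frame(dmps), BASE / "dmps.tsv")
    write_table(volcano_table(dmps), BASE / "volcano.tsv")
    coords, frac = sample_pca(matrix, n_components=2)
    write_table(coords.reset_index(), BASE / "pca.tsv")
    with open(BASE / "dmp_summary.json", "w") as fh:
        json.dump(summary.__dict__, fh, indent=2, sort_keys=True)

    truth = json.loads((FIX / "truth.json").read_text())
    sig = {d.probe_id for d in dmps if d.significant}
    spiked = set(truth["spiked_dmp_probes"])
    print(f"{summary.n_significant} significant DMPs "
          f"({summary.n_hyper} hyper / {summary.n_hypo} hypo); "
          f"{summary.n_hyper_large_effect + summary.n_hypo_large_effect} with |Δβ| > 0.15")
    print(f"spiked single-probe effects recovered: {len(spiked & sig)}/{len(spiked)}")
    print(f"PC1/PC2 variance fractions: {frac[0]:.2f} / {frac[1]:.2f}")


if __name__ == "__main__":
    main()
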