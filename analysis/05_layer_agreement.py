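"""Between-layer agreement of defective regions (Cohen's kappa).

Clusters the planted-defect subcohort per layer, classifies clusters as
defective (negative mean below the macula-wide average), binarises the
maps and computes percentage agreement and kappa for GCIPL-INL, GCIPL-ORC
and INL-ORC.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from retclust.agreement import agreement_stats, defective_mask
from retclust.cluster import cluster_grid, participant_feature_matrix, subcohort_mean_grid
from retclust.experiments import _deviation_grids
from retclust.types import LAYERS

HERE = Path(__file__).resolve().parent
spec = importlib.util.spec_from_file_location("dev03", HERE / "03_deviation_maps.py")
dev03 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(dev03)

RESULTS = HERE.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    healthy, glaucoma = dev03.build_subcohort()
    grids = _deviation_grids(glaucoma, healthy)
    masks, valids = {}, {}
    for layer in LAYERS:
        layer_grids = list(grids[layer].values())
        mean, valid = subcohort_mean_grid(layer_grids)
        sol = cluster_grid(mean, valid,
                           feature_matrix=participant_feature_matrix(layer_grids, valid))
        masks[layer] = defective_mask(sol, mean, valid)
        valids[layer] = valid
    rows = []
    for la, lb in (("GCIPL", "INL"), ("GCIPL", "ORC"), ("INL", "ORC")):
        res = agreement_stats(masks[la], masks[lb],
                              valid=valids[la] & valids[lb], layer_pair=(la, lb))
        rows.append({
            "pair": f"{la}-{lb}",
            "percent_agreement": round(res.percent_agreement, 1),
            "kappa": "N/A" if res.kappa is None else round(res.kappa, 3),
            "p_value": "N/A" if res.p_value is None else f"{res.p_value:.2g}",
            "n_cells": res.n,
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "layer_agreement.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
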