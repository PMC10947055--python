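"""10-2 visual-field defect classification.

Defect clusters follow the Hodapp-Parrish-Anderson reading: at least three
contiguous points of the pattern-deviation probability map flagged at
p < 5%, with at least one of them at p < 1%.  Contiguity is 8-connectivity
on the 2-degree lattice.  Fields are then typed as clear (C), inferior (I),
superior (S) or ring (R), and stratified by mean deviation in 3 dB bins.

Conventions: field y > 0 is the superior hemifield; x < 0 is the nasal half
of the field (right-eye format, x > 0 temporal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import FLAG_P1, FLAG_P5, VFResult

logger = logging.getLogger(__name__)

MD_BINS = ("bin1", "bin2", "bin3", "bin4")


@dataclass
class DefectClassification:
    defect_type: str  # C, I, S or R
    md_bin: str
    clusters: list = field(default_factory=list)  # list of point-index lists

    def __post_init__(self) -> None:
        if (self.defect_type == "C") != (len(self.clusters) == 0):
            raise ValueError("type C iff no qualifying clusters")


def find_vf_defect_clusters(vf: VFResult) -> list[list[int]]:
    """Connected components of flagged points that qualify as defect clusters.

    Components are built over points flagged at p < 5% or worse under
    8-connectivity (lattice neighbours within 2 degrees on each axis); a
    component qualifies iff it has >= 3 points and >= 1 point at p < 1% or
    worse.  Returns lists of row indices into ``vf.points``.
    """
    pts = vf.points.reset_index(drop=True)
    flagged = np.flatnonzero(pts["flag"].to_numpy() >= FLAG_P5)
    if flagged.size == 0:
        return []
    xy = pts.loc[flagged, ["x", "y"]].to_numpy()
    n = len(flagged)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if abs(xy[i, 0] - xy[j, 0]) <= 2 and abs(xy[i, 1] - xy[j, 1]) <= 2:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(int(flagged[i]))
    clusters = []
    flags = pts["flag"].to_numpy()
    for members in comps.values():
        if len(members) >= 3 and np.any(flags[members] >= FLAG_P1):
            clusters.append(sorted(members))
    clusters.sort(key=lambda m: (-len(m), m))
    return clusters


def _is_arcuate(cluster: list[int], pts: pd.DataFrame) -> bool:
    """Arcuate test: the cluster reaches nasally and loss is deeper nasally.

    Operationalised as: the cluster contains nasal points (x < 0) and the
    mean pattern deviation over its nasal half is <= the mean over its
    temporal half (deeper loss nasally).  A cluster with no temporal points
    passes trivially.
    """
    sub = pts.loc[cluster]
    nasal = sub[sub["x"] < 0]
    temporal = sub[sub["x"] > 0]
    if nasal.empty:
        return False
    if temporal.empty:
        return True
    return nasal["pd"].mean() <= temporal["pd"].mean()


def classify_defect_type(clusters: list[list[int]], vf: VFResult) -> str:
    """Type a field as C, I, S or R from its qualifying defect clusters.

    A cluster straddling the horizontal meridian (adjacent rows y = +-1 are
    8-connected) is analysed through its hemifield parts: a part counts as a
    hemifield defect when it would itself qualify (>= 3 points, >= 1 at
    p < 1%).  Ring fields need a qualifying, arcuate part in each hemifield.
    """
    if not clusters:
        return "C"
    pts = vf.points.reset_index(drop=True)
    y = pts["y"].to_numpy()
    flags = pts["flag"].to_numpy()
    defect_points = sorted({i for c in clusters for i in c})
    n_sup = int(np.sum(y[defect_points] > 0))
    n_inf = int(np.sum(y[defect_points] < 0))
    # single-hemifield defect with at most one encroaching point
    if n_inf <= 1:
        return "S"
    if n_sup <= 1:
        return "I"
    # both hemifields substantially involved: split clusters into hemifield
    # parts and re-apply the qualification rule per part
    parts = []
    for c in clusters:
        for hemi, sel in (("S", [i for i in c if y[i] > 0]),
                          ("I", [i for i in c if y[i] < 0])):
            if sel:
                qualifies = len(sel) >= 3 and bool(np.any(flags[sel] >= FLAG_P1))
                parts.append((hemi, sel, qualifies))
    sup_ok = [p for p in parts if p[0] == "S" and p[2]]
    inf_ok = [p for p in parts if p[0] == "I" and p[2]]
    if sup_ok and inf_ok:
        if any(_is_arcuate(p[1], pts) for p in sup_ok) and any(
            _is_arcuate(p[1], pts) for p in inf_ok
        ):
            return "R"
    # otherwise the hemifield of the larger part wins (ties: more negative
    # mean pattern deviation, logged)
    sizes = [len(p[1]) for p in parts]
    best = max(range(len(parts)), key=lambda i: sizes[i])
    tied = [i for i in range(len(parts)) if sizes[i] == sizes[best]]
    if len(tied) > 1:
        means = [pts.loc[parts[i][1], "pd"].mean() for i in tied]
        best = tied[int(np.argmin(means))]
        logger.info("tie in larger-cluster rule broken by mean pattern deviation")
    return parts[best][0]


def assign_md_bin(md: float) -> str:
    """3 dB severity bins; a boundary value goes to the worse bin."""
    if not np.isfinite(md):
        raise ValueError("MD must be finite")
    if md > -3.0:
        return "bin1"
    if md > -6.0:
        return "bin2"
    if md > -9.0:
        return "bin3"
    return "bin4"


def classify_vf(vf: VFResult) -> DefectClassification:
    clusters = find_vf_defect_clusters(vf)
    return DefectClassification(
        defect_type=classify_defect_type(clusters, vf),
        md_bin=assign_md_bin(vf.md),
        clusters=clusters,
    )
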