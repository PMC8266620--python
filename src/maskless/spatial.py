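"""Spatial statistics: error rates as a function of position on the array.

Per-feature error profiles are mapped onto DMD coordinates (reported as
feature-grid cell indices), summarized over four concentric rectangular
areas (area 1 = center, area 4 = outer ring including the corners), and
screened for clusters of unreadable features (e.g. the signature of a
missing UV-absorber meniscus in one corner).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .layout import ArrayLayout, concentric_area_of
from .profiler import DEL, SUB, TRUNC, EventMatrix


def feature_profiles(em: EventMatrix, layout: ArrayLayout,
                     min_reads: int = 5,
                     n_areas: int = 4) -> pd.DataFrame:
    """Per-feature error rates on DMD coordinates (the spatial error map).

    One row per layout feature.  Rates are % per covered bp over the
    feature's readable reads; features with fewer than *min_reads* readable
    reads are flagged low-coverage, features with no reads at all missing.
    Raw event counts are kept so that any aggregation of the map reproduces
    the pooled rates exactly.
    """
    if em.feature_ids is None:
        raise ValueError("event matrix carries no feature ids")
    fid_arr = np.asarray(em.feature_ids)
    known = set(layout.feature_ids)
    unknown = [f for f in set(em.feature_ids) if f not in known]
    if unknown:
        raise ValueError(f"reads reference unknown features: {unknown[:5]}")

    covered = (em.codes != TRUNC).sum(axis=1)
    n_del = (em.codes == DEL).sum(axis=1)
    n_sub = (em.codes == SUB).sum(axis=1)
    n_ins = np.zeros(em.n_reads, dtype=int)
    np.add.at(n_ins, em.ins_read, em.ins_len)

    rows = []
    for f in layout.features:
        sel = fid_arr == f.feature_id
        readable = sel & em.readable
        denom = int(covered[readable].sum())
        cr, cc = layout.cell_of(f.feature_id)
        rec = {
            "feature_id": f.feature_id,
            "row": f.top_row, "col": f.left_col,
            "cell_row": cr, "cell_col": cc,
            "area": concentric_area_of(layout, f.feature_id, n_areas),
            "n_reads": int(sel.sum()),
            "n_readable": int(readable.sum()),
            "n_ref_bases": denom,
            "n_deletions": int(n_del[readable].sum()),
            "n_insertions": int(n_ins[readable].sum()),
            "n_substitutions": int(n_sub[readable].sum()),
        }
        if denom > 0:
            rec["deletion"] = 100.0 * rec["n_deletions"] / denom
            rec["insertion"] = 100.0 * rec["n_insertions"] / denom
            rec["substitution"] = 100.0 * rec["n_substitutions"] / denom
        else:
            rec["deletion"] = rec["insertion"] = rec["substitution"] = np.nan
        rec["low_coverage"] = rec["n_readable"] < min_reads
        rec["missing"] = rec["n_reads"] == 0
        rows.append(rec)
    return pd.DataFrame(rows)


def area_summary(spatial_map: pd.DataFrame) -> pd.DataFrame:
    """Per-area error rates (weighted by covered reference bases) and counts.

    Weighting by bases makes the all-area aggregate identical to the global
    per-bp rates.
    """
    rows = []
    for area, grp in spatial_map.groupby("area"):
        denom = grp["n_ref_bases"].sum()
        rec = {"area": area,
               "n_features": len(grp),
               "n_missing": int(grp["missing"].sum()),
               "n_low_coverage": int(grp["low_coverage"].sum()),
               "n_ref_bases": int(denom)}
        for metric, col in (("deletion", "n_deletions"),
                            ("insertion", "n_insertions"),
                            ("substitution", "n_substitutions")):
            rec[metric] = (100.0 * grp[col].sum() / denom if denom else np.nan)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("area")


def detect_unreadable(spatial_map: pd.DataFrame, min_reads: int = 5
                      ) -> tuple[pd.DataFrame, list[dict]]:
    """Features without enough readable reads, plus contiguous blobs.

    Returns the unreadable feature rows and a list of spatially contiguous
    clusters (8-connectivity on the feature grid), each with a feature count
    and cell-coordinate bounding box -- large rectangular blobs are the
    signature of a locally dead optical path.
    """
    bad = spatial_map[spatial_map["n_readable"] < min_reads]
    gr = spatial_map["cell_row"].max() + 1
    gc = spatial_map["cell_col"].max() + 1
    grid = np.zeros((gr, gc), dtype=bool)
    grid[bad["cell_row"], bad["cell_col"]] = True
    labels, n = ndimage.label(grid, structure=np.ones((3, 3), dtype=int))
    blobs = []
    for lab in range(1, n + 1):
        rr, cc = np.nonzero(labels == lab)
        blobs.append({
            "n_features": int(rr.size),
            "cell_row_min": int(rr.min()), "cell_row_max": int(rr.max()),
            "cell_col_min": int(cc.min()), "cell_col_max": int(cc.max()),
        })
    blobs.sort(key=lambda b: -b["n_features"])
    return bad, blobs


def export_heatmap(spatial_map: pd.DataFrame, metric: str,
                   path=None, log_scale: bool = False,
                   sentinel: float = -1.0) -> pd.DataFrame:
    """Feature-grid heatmap of a metric; missing cells carry the sentinel.

    *metric* is one of deletion / insertion / substitution / reads.  With
    ``log_scale`` the values are log10(1 + x) (used for read-count maps).
    Writes a TSV grid when *path* is given.
    """
    col = {"deletion": "deletion", "insertion": "insertion",
           "substitution": "substitution", "reads": "n_readable"}.get(metric)
    if col is None:
        raise ValueError(f"unknown metric {metric!r}")
    gr = spatial_map["cell_row"].max() + 1
    gc = spatial_map["cell_col"].max() + 1
    grid = np.full((gr, gc), sentinel, dtype=float)
    vals = spatial_map[col].to_numpy(dtype=float)
    if log_scale:
        vals = np.log10(1.0 + vals)
    ok = ~np.isnan(vals)
    grid[spatial_map["cell_row"].to_numpy()[ok],
         spatial_map["cell_col"].to_numpy()[ok]] = vals[ok]
    df = pd.DataFrame(grid)
    if path is not None:
        df.to_csv(path, sep="\t", header=False, index=False,
                  float_format="%.6g")
    return df


def area_contrast_test(spatial_map: pd.DataFrame, metric: str,
                       area_a: int = 1, area_b: int = 4,
                       n_perm: int = 2000, seed: int = 0) -> dict:
    """Permutation test of the area_b - area_a difference in a rate metric.

    The observed difference of base-weighted mean rates is compared with the
    null distribution obtained by shuffling area labels across features.
    Returns the observed difference (% per bp) and the two-sided p-value.
    """
    count_col = {"deletion": "n_deletions", "insertion": "n_insertions",
                 "substitution": "n_substitutions"}[metric]
    sub = spatial_map[spatial_map["area"].isin([area_a, area_b])]
    sub = sub[sub["n_ref_bases"] > 0]
    counts = sub[count_col].to_numpy(dtype=float)
    bases = sub["n_ref_bases"].to_numpy(dtype=float)
    in_b = (sub["area"] == area_b).to_numpy()

    def diff(mask_b: np.ndarray) -> float:
        rb = counts[mask_b].sum() / bases[mask_b].sum()
        ra = counts[~mask_b].sum() / bases[~mask_b].sum()
        return 100.0 * (rb - ra)

    observed = diff(in_b)
    rng = np.random.default_rng(seed)
    n_b = int(in_b.sum())
    hits = 0
    idx = np.arange(len(sub))
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        mask = np.zeros(len(sub), dtype=bool)
        mask[perm[:n_b]] = True
        if abs(diff(mask)) >= abs(observed):
            hits += 1
    return {"difference": observed, "p_value": (hits + 1) / (n_perm + 1),
            "n_features": len(sub)}
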