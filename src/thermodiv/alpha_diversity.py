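"""Taxonomic alpha-diversity estimators: Chao1, Shannon, inverse Simpson.

All estimators take a vector of OTU counts for one unit (a sample, or a
site after pooling).  Zero-count entries are ignored — an OTU absent from a
unit is not a species of that unit.  Shannon entropy uses natural logs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["chao1", "shannon", "inv_simpson", "alpha_profile"]


def _positive(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size == 0 or not np.all(np.isfinite(c)) or np.any(c < 0):
        raise ValueError("counts must be finite and nonnegative")
    if np.any(c != np.floor(c)):
        raise ValueError("counts must be integers")
    c = c[c > 0]
    if c.size == 0:
        raise ValueError("all-zero count vector: diversity undefined")
    return c.astype(np.int64)


def chao1(counts) -> float:
    """Chao1 estimated richness from singleton and doubleton counts.

    S_chao1 = S_obs + f1^2 / (2 f2), where f1 and f2 are the numbers of
    OTUs seen exactly once and exactly twice.  When f2 = 0 the
    bias-corrected form S_obs + f1 (f1 - 1) / (2 (f2 + 1)) is used so the
    estimate stays finite; it reduces to S_obs when f1 <= 1.
    """
    c = _positive(counts)
    s_obs = c.size
    f1 = int(np.sum(c == 1))
    f2 = int(np.sum(c == 2))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts) -> float:
    """Shannon-Weaver entropy H = -sum p_i ln p_i (nats)."""
    c = _positive(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def inv_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum p_i^2 — effective species count."""
    c = _positive(counts)
    p = c / c.sum()
    return float(1.0 / (p * p).sum())


def alpha_profile(table, level: str = "sample", tree=None) -> pd.DataFrame:
    """Alpha-diversity table: one row per sample (or per site after pooling).

    Columns: s_obs, f1, f2, chao1, shannon, inv_simpson and, when a tree is
    supplied, faith_pd.  The net relatedness index lives in
    :mod:`thermodiv.phylo_diversity` (it needs a null model and a seed) and
    is merged in by the pipeline.
    """
    from .tables_io import pool_by_site

    if level == "site":
        table = pool_by_site(table)
    elif level != "sample":
        raise ValueError(f"level must be 'sample' or 'site', got {level!r}")
    if tree is not None:
        from .phylo_diversity import faith_pd as _faith

    rows = []
    for unit in table.sample_ids:
        col = table.counts[unit].to_numpy()
        pos = col[col > 0]
        row = {
            "unit": unit,
            "s_obs": int(pos.size),
            "f1": int(np.sum(pos == 1)),
            "f2": int(np.sum(pos == 2)),
            "chao1": chao1(col),
            "shannon": shannon(col),
            "inv_simpson": inv_simpson(col),
        }
        if tree is not None:
            present = {o for o, n in zip(table.otu_ids, col) if n > 0}
            row["faith_pd"] = _faith(tree, present)
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit")
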