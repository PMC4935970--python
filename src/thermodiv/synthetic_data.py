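"""Synthetic multi-site metacommunities with a known activation energy.

The generator emulates a continental transect of forest soil communities:
six sites spanning mean annual temperatures 2.5-25.7 degC, 21 replicate
samples per site, site-level true richness following the Boltzmann-
Arrhenius law ln S = a - E_a/(kT), a lognormal species-abundance
distribution (singleton-rich tails, so Chao1 exceeds observed richness),
multinomial read sampling at depths in the tens of thousands, a random
phylogeny over the species pool, and environmental covariates generated as
linear functions of temperature plus Gaussian noise.

Every stochastic component draws from a named substream of one seed, so
tree, abundances, read sampling and covariates are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .mte_models import BOLTZMANN_EV_PER_K
from .tables_io import OtuTable, SampleMetadata

__all__ = [
    "SimConfig",
    "site_richness",
    "generate_tree",
    "generate_dataset",
    "merge_sister_otus",
    "dataset_truth",
]


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic transect.

    Defaults mirror the emulated survey: 6 sites at 2.5-25.7 degC, 21
    samples per site, 20,000 reads per sample, true activation energy
    0.25 eV with intercept a = 17 (site richness ~650-1450).
    """

    temps_c: tuple[float, ...] = (2.5, 7.0, 12.0, 17.0, 21.0, 25.7)
    samples_per_site: int = 21
    true_ea: float = 0.25
    intercept_a: float = 17.0
    depth: int = 20_000
    sad_meanlog: float = 0.0
    sad_sdlog: float = 1.5
    abundance_jitter_sd: float = 0.5
    env_noise: float = 0.3
    pool_mode: str = "nested"  # or "disjoint"
    seed: int = 0

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.temps_c)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("temps_c must be strictly increasing")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.true_ea < 0:
            raise ValueError("true_ea must be >= 0")
        if self.samples_per_site < 1:
            raise ValueError("samples_per_site must be >= 1")
        if self.pool_mode not in {"nested", "disjoint"}:
            raise ValueError("pool_mode must be 'nested' or 'disjoint'")
        self.temps_c = temps

    @property
    def n_sites(self) -> int:
        return len(self.temps_c)

    @property
    def site_ids(self) -> list[str]:
        return [f"site{i+1}" for i in range(self.n_sites)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "temps_c" in raw:
            raw["temps_c"] = tuple(raw["temps_c"])
        return cls(**raw)


def site_richness(cfg: SimConfig) -> pd.Series:
    """True per-site richness S = round(exp(a - E_a/(kT))); must be >= 2."""
    t_k = np.asarray(cfg.temps_c) + 273.15
    s = np.round(np.exp(cfg.intercept_a - cfg.true_ea / (BOLTZMANN_EV_PER_K * t_k)))
    if np.any(s < 2):
        raise ValueError(
            "richness below 2 at some site; increase intercept_a or lower true_ea"
        )
    return pd.Series(s.astype(int), index=cfg.site_ids, name="richness")


def generate_tree(n_tips: int, seed, labels=None) -> TreeNode:
    """Random rooted tree by iterative random pair joining.

    Branch lengths are i.i.d. Exponential(1); tip labels default to
    OTU000001, ... in random attachment order.
    """
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = [f"OTU{i+1:06d}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("label count must equal n_tips")
    nodes = [TreeNode(name=l) for l in labels]
    rng.shuffle(nodes)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i > j else (int(j), int(i))
        a, b = nodes.pop(i), nodes.pop(j)
        a.length = float(max(rng.exponential(), 1e-9))
        b.length = float(max(rng.exponential(), 1e-9))
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def _site_pools(cfg: SimConfig, s_site: pd.Series) -> tuple[int, dict[str, np.ndarray]]:
    if cfg.pool_mode == "nested":
        # warmer (richer) sites extend the colder sites' pool
        n_pool = int(s_site.max())
        pools = {site: np.arange(int(s)) for site, s in s_site.items()}
    else:
        offsets = np.concatenate([[0], np.cumsum(s_site.to_numpy())])
        n_pool = int(offsets[-1])
        pools = {
            site: np.arange(offsets[i], offsets[i + 1])
            for i, site in enumerate(s_site.index)
        }
    return n_pool, pools


def generate_dataset(cfg: SimConfig) -> tuple[OtuTable, TreeNode, SampleMetadata]:
    """Simulate the OTU table, phylogeny and metadata for one transect.

    Per site, species relative abundances are a global lognormal SAD
    restricted to the site's pool and jittered on the log scale
    (``abundance_jitter_sd``) to create compositional turnover beyond
    nestedness; each sample is a multinomial draw of ``depth`` reads.
    """
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("tree", "sad", "sampling", "env"),
            np.random.SeedSequence(cfg.seed).spawn(4),
        )
    }
    s_site = site_richness(cfg)
    n_pool, pools = _site_pools(cfg, s_site)
    otu_ids = [f"OTU{i+1:06d}" for i in range(n_pool)]

    sad = streams["sad"]
    w_global = sad.lognormal(cfg.sad_meanlog, cfg.sad_sdlog, size=n_pool)

    sampling = streams["sampling"]
    counts = np.zeros((n_pool, cfg.n_sites * cfg.samples_per_site), dtype=np.int64)
    sample_ids, site_of = [], {}
    col = 0
    for site in cfg.site_ids:
        pool = pools[site]
        w = w_global[pool] * np.exp(
            sad.normal(0.0, cfg.abundance_jitter_sd, size=pool.size)
        )
        p = w / w.sum()
        for rep in range(cfg.samples_per_site):
            sid = f"{site}_s{rep+1:02d}"
            counts[pool, col] = sampling.multinomial(cfg.depth, p)
            sample_ids.append(sid)
            site_of[sid] = site
            col += 1

    table = OtuTable(
        pd.DataFrame(counts, index=otu_ids, columns=sample_ids), site_of=site_of
    )
    tree = generate_tree(n_pool, streams["tree"], labels=otu_ids)
    meta = _generate_metadata(cfg, streams["env"], sample_ids, site_of)
    return table, tree, meta


#: Site-level covariate models: value = intercept + slope * T_c + N(0, sd * env_noise).
_COVARIATE_MODELS = {
    "precipitation_mm": (600.0, 55.0, 400.0),
    "ph": (6.8, -0.08, 0.8),
    "moisture_pct": (18.0, 0.6, 8.0),
    "total_c": (8.0, -0.15, 2.0),
    "total_n": (0.55, -0.01, 0.12),
    "plant_richness": (8.0, 5.5, 30.0),
}
#: Covariates measured per sample; they get extra within-site noise at a
#: quarter of the between-site scale.
_SAMPLE_LEVEL = ("ph", "moisture_pct", "total_c", "total_n")


def _generate_metadata(cfg, rng, sample_ids, site_of) -> SampleMetadata:
    temps = dict(zip(cfg.site_ids, cfg.temps_c))
    site_vals: dict[str, dict[str, float]] = {s: {} for s in cfg.site_ids}
    for var, (b0, b1, sd) in _COVARIATE_MODELS.items():
        for site in cfg.site_ids:
            site_vals[site][var] = (
                b0 + b1 * temps[site] + rng.normal(0.0, sd * cfg.env_noise)
            )
    rows = []
    for sid in sample_ids:
        site = site_of[sid]
        row = {"sample_id": sid, "site_id": site, "temperature_c": temps[site]}
        for var, (_, _, sd) in _COVARIATE_MODELS.items():
            val = site_vals[site][var]
            if var in _SAMPLE_LEVEL:
                val += rng.normal(0.0, 0.25 * sd * cfg.env_noise)
            row[var] = round(val) if var == "plant_richness" else val
        rows.append(row)
    df = pd.DataFrame(rows).set_index("sample_id")
    df["plant_richness"] = df["plant_richness"].clip(lower=1)
    return SampleMetadata(df)


def merge_sister_otus(t: OtuTable, tree: TreeNode) -> OtuTable:
    """Coarsen taxonomic resolution by collapsing every sister-tip pair.

    Each cherry (an internal node whose two children are both tips) becomes
    one OTU whose counts are the pair's sum — a stand-in for re-clustering
    sequences at a lower similarity cutoff.  Counts are conserved.
    """
    merge_into: dict[str, str] = {}
    for node in tree.non_tips(include_self=True):
        kids = node.children
        if len(kids) == 2 and all(k.is_tip() for k in kids):
            a, b = sorted(k.name for k in kids)
            merge_into[b] = a
    counts = t.counts.copy()
    index = counts.index
    target = [merge_into.get(o, o) for o in index]
    merged = counts.groupby(pd.Index(target, name=index.name or "otu_id"), sort=False).sum()
    merged = merged.loc[[o for o in index if o not in merge_into]]
    return OtuTable(merged, site_of=t.site_of)


def dataset_truth(cfg: SimConfig) -> dict:
    """Ground-truth record for a generated dataset (for truth.json)."""
    return {
        "true_ea": cfg.true_ea,
        "intercept_a": cfg.intercept_a,
        "site_richness": site_richness(cfg).to_dict(),
        "config": cfg.to_dict(),
    }
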