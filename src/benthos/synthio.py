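"""Synthetic inputs with known ground truth.

Emulates the study design the pipeline expects: a 2 (land use) x 2 (rain
event) x 2 (before/after) x n-replicate factorial of sediment samples,
Dirichlet-multinomial community profiles with controllable land-use and
rain effect sizes, per-read protein-search hit lists with decoys and
low-complexity reads, shotgun reads with embedded degenerate-primer V6
tags, and environmental series with prescribed Kendall correlation to
rain.

All randomness flows from one integer seed, expanded into per-operation
substreams through fixed ``SeedSequence`` spawn keys (the counter scheme
documented in :data:`OP_KEYS`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import stats

from .taxbin import RANKS, ReadHitSet, TaxonomyTree

__all__ = [
    "OP_KEYS",
    "SimulationParams",
    "generate_metadata",
    "generate_taxonomy",
    "generate_profiles_and_hits",
    "hits_to_readsets",
    "generate_v6_reads",
    "generate_env_rain",
    "V6_PRIMER",
]

#: Fixed substream keys: rng(seed, operation) is reproducible and
#: independent across operations.
OP_KEYS = {"taxonomy": 0, "profiles": 1, "hits": 2, "v6": 3, "env": 4}

#: Universal V6 primer used for ribotag extraction (R = A/G, N = any).
V6_PRIMER = "CGACRRCCATGCANCACCT"

_IUPAC_CHOICES = {"A": "A", "C": "C", "G": "G", "T": "T",
                  "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
                  "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
                  "H": "ACT", "V": "ACG", "N": "ACGT"}


def _rng(seed: int, op: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(OP_KEYS[op],)))


def generate_metadata(n_reps: int) -> pd.DataFrame:
    """Full-factorial sample sheet: land use x rain event x timing x reps.

    n_reps=6 reproduces the 48-sample design.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    for lu in ("industrial", "residential"):
        for re_ in ("RE1", "RE2"):
            for timing in ("before", "after"):
                for rep in range(1, n_reps + 1):
                    sid = f"{lu[0].upper()}_{re_}_{'pre' if timing == 'before' else 'post'}_{rep:02d}"
                    rows.append((sid, lu, re_, timing, rep))
    return pd.DataFrame(rows, columns=["sample_id", "land_use", "rain_event",
                                       "timing", "replicate"]).set_index("sample_id")


@dataclass
class SimulationParams:
    """Community and read-level simulation settings.

    Effects are additive on log relative abundance (then renormalized):
    land-use effects are applied with +/- 1/2 coding (residential high),
    rain effects likewise (after-rain high).  ``dirichlet_concentration``
    scales the compositional noise (larger = tighter around the expected
    composition).  Default library size mirrors the study's mean mapped
    depth scaled down three orders of magnitude.
    """
    n_reps: int = 6
    n_taxa: int = 120
    base_composition: np.ndarray | None = None
    landuse_log_effects: np.ndarray | float = 0.0
    rain_log_effects: np.ndarray | float = 0.0
    dirichlet_concentration: float = 200.0
    library_sizes: np.ndarray | int = 30_000
    decoy_rate: float = 0.0
    nohit_rate: float = 0.0
    lowcomplexity_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.decoy_rate, self.nohit_rate, self.lowcomplexity_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.nohit_rate + self.lowcomplexity_rate > 1:
            raise ValueError("nohit_rate + lowcomplexity_rate must be <= 1")
        if self.n_reps < 1 or self.n_taxa < 2:
            raise ValueError("need n_reps >= 1 and n_taxa >= 2")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be positive")
        if self.base_composition is not None:
            p = np.asarray(self.base_composition, float)
            if p.shape != (self.n_taxa,):
                raise ValueError("base_composition length must equal n_taxa")
            if (p < 0).any() or not np.isclose(p.sum(), 1.0):
                raise ValueError("base_composition must be a probability vector")
        if np.any(np.asarray(self.library_sizes) < 1):
            raise ValueError("library_sizes must be positive")

    def effects(self, which: str) -> np.ndarray:
        v = getattr(self, f"{which}_log_effects")
        v = np.asarray(v, float)
        if v.ndim == 0:
            v = np.full(self.n_taxa, float(v))
        if v.shape != (self.n_taxa,):
            raise ValueError(f"{which}_log_effects length must equal n_taxa")
        return v


def generate_taxonomy(n_taxa: int, seed: int = 0) -> TaxonomyTree:
    """Random rank-complete taxonomy with ``n_taxa`` species leaves.

    Every species has ancestors at genus, family, order, class and phylum;
    parents are drawn uniformly with at least two children per level where
    possible, so the LCA of distinct species is informative.
    """
    rng = _rng(seed, "taxonomy")
    sizes = {"species": n_taxa}
    shrink = {"genus": 3, "family": 2, "order": 2, "class": 2, "phylum": 3}
    prev = n_taxa
    for rank in ("genus", "family", "order", "class", "phylum"):
        prev = max(2, prev // shrink[rank])
        sizes[rank] = prev
    parents, ranks, names = {1: 1}, {1: "root"}, {1: "root"}
    next_id = 2
    ids_at: dict[str, list[int]] = {"root": [1]}
    for rank in RANKS[1:]:  # phylum .. species, top-down
        ids_at[rank] = list(range(next_id, next_id + sizes[rank]))
        upper = RANKS[RANKS.index(rank) - 1]
        choices = ids_at[upper]
        for i, nid in enumerate(ids_at[rank]):
            # cycle through parents first so every upper node gets a child
            parent = choices[i % len(choices)] if i < len(choices) \
                else choices[rng.integers(len(choices))]
            parents[nid] = parent
            ranks[nid] = rank
            names[nid] = f"{rank[0]}{nid}"
        next_id += sizes[rank]
    return TaxonomyTree(parents, ranks, names)


def _sample_compositions(metadata: pd.DataFrame, params: SimulationParams,
                         rng: np.random.Generator) -> pd.DataFrame:
    p = params.base_composition
    if p is None:
        # lognormal rank-abundance, fixed by the profile substream
        p = rng.lognormal(mean=0.0, sigma=1.0, size=params.n_taxa)
        p /= p.sum()
    logp = np.log(np.asarray(p, float) + 1e-300)
    d_lu = params.effects("landuse")
    d_rain = params.effects("rain")
    comps = {}
    for sid, row in metadata.iterrows():
        x_lu = 0.5 if row["land_use"] == "residential" else -0.5
        x_t = 0.5 if row["timing"] == "after" else -0.5
        q = np.exp(logp + x_lu * d_lu + x_t * d_rain)
        q /= q.sum()
        alpha = params.dirichlet_concentration * q
        comps[sid] = rng.dirichlet(alpha)
    return pd.DataFrame(comps)


def generate_profiles_and_hits(metadata: pd.DataFrame, params: SimulationParams,
                               tree: TaxonomyTree | None = None,
                               with_hits: bool = True):
    """Ground-truth count matrix plus per-read hit tables.

    Returns ``(truth, hits, reads, tree)``: ``truth`` is the species-by-
    sample count matrix (true taxon of every read, including reads later
    lost to the no-hit or complexity filters); ``hits`` has columns
    (read_id, taxon_id, bit_score); ``reads`` has per-read attributes
    (sample_id, true_taxon, complexity, category).  With
    ``with_hits=False`` the hit tables are skipped (profiles only).

    Per read: the true species hit scores uniformly in [50, 70]; a decoy
    hit (random other species) lands inside the 10% top-score band half
    the time (coarsening the LCA) and below it otherwise; a ``nohit``
    read's only hit scores below the LCA score floor; a low-complexity
    read carries a homopolymer-like complexity value below 0.44.
    """
    if tree is None:
        tree = generate_taxonomy(params.n_taxa, params.seed)
    species = sorted(n for n in tree.parents if tree.rank_of(n) == "species")
    if len(species) != params.n_taxa:
        raise ValueError("taxonomy species count must equal n_taxa")
    rng = _rng(params.seed, "profiles")
    comps = _sample_compositions(metadata, params, rng)
    lib = np.asarray(params.library_sizes)
    if lib.ndim == 0:
        lib = np.full(len(metadata), int(lib))
    if lib.shape != (len(metadata),):
        raise ValueError("library_sizes must be scalar or one per sample")

    truth = {}
    for i, sid in enumerate(metadata.index):
        truth[sid] = rng.multinomial(int(lib[i]), comps[sid].values)
    truth_df = pd.DataFrame(truth, index=[tree.names[s] for s in species],
                            dtype=float)
    truth_df.index.name = "taxon"
    if not with_hits:
        return truth_df, None, None, tree

    hrng = _rng(params.seed, "hits")
    hit_rows, read_rows = [], []
    spp = np.asarray(species)
    for i, sid in enumerate(metadata.index):
        counts = truth[sid]
        taxa = np.repeat(spp, counts)
        n_reads = taxa.size
        cat = hrng.choice(3, size=n_reads,
                          p=[params.lowcomplexity_rate, params.nohit_rate,
                             1 - params.lowcomplexity_rate - params.nohit_rate])
        decoy = hrng.random(n_reads) < params.decoy_rate
        for r in range(n_reads):
            rid = f"{sid}_r{r:07d}"
            true_t = int(taxa[r])
            if cat[r] == 0:      # low-complexity: filtered before LCA
                complexity = float(hrng.uniform(0.05, 0.35))
                hit_rows.append((rid, true_t, float(hrng.uniform(50, 70))))
            elif cat[r] == 1:    # no qualifying hit
                complexity = 1.0
                hit_rows.append((rid, true_t, float(hrng.uniform(10, 30))))
            else:
                complexity = 1.0
                s = float(hrng.uniform(50, 70))
                hit_rows.append((rid, true_t, s))
                if decoy[r]:
                    other = int(spp[hrng.integers(len(spp))])
                    if hrng.random() < 0.5:
                        ds = float(hrng.uniform(0.92 * s, s))   # in top band
                    else:
                        ds = float(hrng.uniform(36.0, 0.85 * s))  # filtered
                    hit_rows.append((rid, other, ds))
            read_rows.append((rid, sid, true_t, complexity,
                              ("lowcomplexity", "nohit", "ok")[cat[r]]))
    hits = pd.DataFrame(hit_rows, columns=["read_id", "taxon_id", "bit_score"])
    reads = pd.DataFrame(read_rows, columns=["read_id", "sample_id",
                                             "true_taxon", "complexity",
                                             "category"]).set_index("read_id")
    return truth_df, hits, reads, tree


def hits_to_readsets(hits: pd.DataFrame, reads: pd.DataFrame):
    """Group hit rows into per-sample ReadHitSet streams.

    Yields ``(sample_id, list[ReadHitSet])`` in sample order.
    """
    by_read: dict[str, list[tuple[int, float]]] = {}
    for rid, tid, score in hits.itertuples(index=False):
        by_read.setdefault(rid, []).append((int(tid), float(score)))
    for sid, sub in reads.groupby("sample_id", sort=True):
        yield sid, [ReadHitSet(rid, by_read.get(rid, []),
                               float(sub.at[rid, "complexity"]))
                    for rid in sub.index]


def _instantiate(primer: str, rng: np.random.Generator) -> str:
    return "".join(c if c in "ACGT"
                   else _IUPAC_CHOICES[c][rng.integers(len(_IUPAC_CHOICES[c]))]
                   for c in primer)


def generate_v6_reads(n_reads: int, tag_catalogue: list[str],
                      tag_probs, embed_rate: float = 1.0,
                      revcomp_rate: float = 0.0, seed: int = 0,
                      read_length: int = 101, sample_id: str = "S1"):
    """Shotgun reads with V6 primer+tag insertions on a random background.

    An ``embed_rate`` fraction of reads carry an instantiation of the
    degenerate V6 primer immediately followed by a catalogue tag (the full
    33 nt always fits); a ``revcomp_rate`` fraction of those are placed on
    the reverse strand.  Background bases are i.i.d. uniform, so the
    complexity filter never fires on them.  Returns ``(records, truth)``
    with ``truth`` rows (read_id, tag, strand).
    """
    for t in tag_catalogue:
        if len(t) != 33 or set(t) - set("ACGT"):
            raise ValueError(f"catalogue tag {t!r} is not a 33-mer over ACGT")
    probs = np.asarray(tag_probs, float)
    if probs.shape != (len(tag_catalogue),) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("tag_probs must be a probability vector over the catalogue")
    insert_len = len(V6_PRIMER) + 33
    if read_length < insert_len:
        raise ValueError(f"read_length must be >= {insert_len}")
    rng = _rng(seed, "v6")
    records, truth_rows = [], []
    bases = np.array(list("ACGT"))
    for r in range(n_reads):
        rid = f"{sample_id}_v6_{r:06d}"
        seq = "".join(rng.choice(bases, size=read_length))
        tag, strand = None, "."
        if rng.random() < embed_rate:
            k = int(rng.choice(len(tag_catalogue), p=probs))
            tag = tag_catalogue[k]
            insert = _instantiate(V6_PRIMER, rng) + tag
            pos = int(rng.integers(0, read_length - insert_len + 1))
            seq = seq[:pos] + insert + seq[pos + insert_len:]
            strand = "+"
            if rng.random() < revcomp_rate:
                seq = str(Seq(seq).reverse_complement())
                strand = "-"
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [40] * len(seq)
        records.append(rec)
        truth_rows.append((rid, tag, strand))
    truth = pd.DataFrame(truth_rows, columns=["read_id", "tag", "strand"]
                         ).set_index("read_id")
    return records, truth


def generate_env_rain(n_time: int, target_tau, seed: int = 0):
    """Rain series plus environmental variables with prescribed Kendall tau.

    Uses a Gaussian copula: latent correlation rho = sin(pi * tau / 2)
    gives population Kendall tau equal to ``target_tau`` for the
    (continuous, monotone-transformed) margins, so the sample tau-b
    converges to the target as ``n_time`` grows.  ``target_tau`` may be a
    scalar or a mapping of variable name -> tau.
    """
    if n_time < 3:
        raise ValueError("need at least 3 time points")
    taus = target_tau if isinstance(target_tau, dict) else {"env": float(target_tau)}
    for name, t in taus.items():
        if not -1 <= t <= 1:
            raise ValueError(f"|target_tau| must be <= 1 (got {t} for {name})")
    rng = _rng(seed, "env")
    z_rain = rng.standard_normal(n_time)
    # gamma-distributed daily rain intensities (mm), strictly increasing in z
    rain = stats.gamma.ppf(stats.norm.cdf(z_rain), a=0.8, scale=12.0)
    env = {}
    for name, tau in taus.items():
        rho = np.sin(np.pi * tau / 2)
        z = rho * z_rain + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(n_time)
        env[name] = 20.0 + 5.0 * z  # arbitrary monotone scale
    idx = pd.RangeIndex(n_time, name="day")
    return pd.Series(rain, index=idx, name="rain_mm"), pd.DataFrame(env, index=idx)
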