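"""Synthetic guano-metabarcoding dataset generator with ground truth.

Emulates the sampling design the analysis modules expect: five colonies
(one highland with a partly private prey pool) monitored over eleven
biweekly dates spanning three seasons, community samples pooling 15-20
pellets plus 3-pellet small replicates, lognormal amplification bias,
sub-threshold sequencing-error MOTUs, and blank-borne contaminants.

All randomness flows from one master seed through labeled sub-streams
(SHA-256 of the label mixed into the seed sequence), so adding a stage
never perturbs another stage's draws and identical configs are
bit-reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .read_pipeline import MotuTable, SequenceRead, TaxonRecord

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "build_species_pools",
    "sample_pellets",
    "simulate_reads",
    "inject_artifacts",
    "generate_dataset",
    "random_amplicon",
    "simulate_read_pairs",
]

SEASONS = ("spring", "summer", "autumn")

# family catalogue: (class, order, family, sampling weight) — moth- and
# fly-dominated, mirroring a temperate gleaning bat's prey spectrum
FAMILY_CATALOGUE: tuple[tuple[str, str, str, float], ...] = (
    ("Insecta", "Lepidoptera", "Noctuidae", 18.0),
    ("Insecta", "Lepidoptera", "Geometridae", 12.0),
    ("Insecta", "Lepidoptera", "Erebidae", 8.0),
    ("Insecta", "Lepidoptera", "Tortricidae", 6.0),
    ("Insecta", "Lepidoptera", "Crambidae", 4.0),
    ("Insecta", "Lepidoptera", "Sphingidae", 2.0),
    ("Insecta", "Lepidoptera", "Pyralidae", 2.0),
    ("Insecta", "Diptera", "Tipulidae", 8.0),
    ("Insecta", "Diptera", "Limoniidae", 6.0),
    ("Insecta", "Diptera", "Muscidae", 5.0),
    ("Insecta", "Diptera", "Chironomidae", 4.0),
    ("Insecta", "Diptera", "Syrphidae", 3.0),
    ("Insecta", "Coleoptera", "Carabidae", 2.0),
    ("Insecta", "Coleoptera", "Scarabaeidae", 1.0),
    ("Insecta", "Hemiptera", "Pentatomidae", 1.5),
    ("Insecta", "Neuroptera", "Chrysopidae", 1.5),
    ("Insecta", "Hymenoptera", "Ichneumonidae", 1.5),
    ("Insecta", "Trichoptera", "Limnephilidae", 1.0),
    ("Arachnida", "Araneae", "Araneidae", 1.5),
    ("Arachnida", "Araneae", "Linyphiidae", 1.0),
    ("Malacostraca", "Isopoda", "Oniscidae", 0.5),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults mirror the emulated study design."""

    n_colonies: int = 5
    n_dates: int = 11
    # date index (1-based) -> season; default 4 spring, 4 summer, 3 autumn
    season_of_date: tuple[str, ...] = (
        "spring", "spring", "spring", "spring",
        "summer", "summer", "summer", "summer",
        "autumn", "autumn", "autumn",
    )
    # per-season available prey pool sizes; summer peak drives the
    # mid-season richness maximum the analysis should recover
    pool_size_per_season: dict[str, int] = field(
        default_factory=lambda: {"spring": 110, "summer": 170, "autumn": 95}
    )
    season_turnover: float = 0.25
    highland_pool_divergence: float = 0.5
    pellets_per_community: tuple[int, int] = (15, 20)
    pellets_per_small: int = 3
    n_small_replicates: int = 6
    prey_per_pellet: float = 4.0
    prey_per_pellet_dispersion: float = 1.5
    date_availability: float = 0.7
    reads_per_sample: int = 16583
    bias_sigma: float = 1.5
    singleton_error_rate: float = 2.0
    contaminant_motus: int = 2
    n_blanks: int = 3
    abundance_sigma: float = 1.0
    biomass_sigma: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("season_turnover", "highland_pool_divergence", "date_availability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_colonies", "n_dates", "pellets_per_small", "reads_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if len(self.season_of_date) != self.n_dates:
            raise ValueError("season map must cover every date")
        if any(s not in SEASONS for s in self.season_of_date):
            raise ValueError(f"seasons must be among {SEASONS}")
        lo, hi = self.pellets_per_community
        if not 1 <= lo <= hi:
            raise ValueError("pellets_per_community must be a valid range")

    @property
    def colonies(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.n_colonies)]

    @property
    def highland_colony(self) -> str:
        return self.colonies[-1]

    @property
    def seasons(self) -> list[str]:
        seen = []
        for s in self.season_of_date:
            if s not in seen:
                seen.append(s)
        return seen

    def pool_size(self, season: str) -> int:
        sizes = self.pool_size_per_season
        if isinstance(sizes, int):
            return sizes
        return sizes[season]


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    # (colony, season) -> ordered species ids
    species_pools: dict[tuple[str, str], list[str]]
    # season -> species id -> abundance weight (fixed within a season)
    abundance_weights: dict[str, dict[str, float]]
    # per-sample consumed-biomass proportions (sum to 1)
    diet_proportions: dict[str, dict[str, float]]
    # species id -> multiplicative amplification bias (> 0)
    bias_factors: dict[str, float]
    # species id -> biomass size factor (> 0)
    size_factors: dict[str, float]
    # MOTU id -> {"genuine", "error", "contaminant"}
    artifact_labels: dict[str, str]

    def genuine_motus(self) -> set[str]:
        return {m for m, lab in self.artifact_labels.items() if lab == "genuine"}


@dataclass
class SyntheticDataset:
    table: MotuTable
    taxonomy: dict[str, TaxonRecord]
    metadata: pd.DataFrame  # indexed by sample id
    truth: SyntheticTruth

    @property
    def blank_ids(self) -> list[str]:
        return list(self.metadata.index[self.metadata["regime"] == "blank"])


def _rng(seed: int, label: str) -> np.random.Generator:
    digest = hashlib.sha256(label.encode()).digest()
    salt = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


def _new_species(counter: list[int], n: int) -> list[str]:
    start = counter[0]
    counter[0] += n
    return [f"sp{start + i + 1:04d}" for i in range(n)]


def build_species_pools(config: SyntheticConfig):
    """Per colony x season species pools plus taxonomy and truth scaffolding.

    Lowland colonies share identical season pools; the highland colony
    replaces a ``highland_pool_divergence`` fraction of each pool with
    private species. Adjacent seasons share a ``season_turnover``
    fraction of the smaller pool; non-adjacent seasons share species only
    through those carried across the intermediate season.
    """
    rng = _rng(config.rng_seed, "pools")
    counter = [0]
    seasons = config.seasons

    base: dict[str, list[str]] = {}
    prev: list[str] | None = None
    for season in seasons:
        size = config.pool_size(season)
        if prev is None:
            pool = _new_species(counter, size)
        else:
            n_shared = round(config.season_turnover * min(size, len(prev)))
            carried = list(rng.choice(prev, size=n_shared, replace=False)) if n_shared else []
            pool = carried + _new_species(counter, size - n_shared)
        base[season] = pool
        prev = pool

    pools: dict[tuple[str, str], list[str]] = {}
    for colony in config.colonies:
        for season in seasons:
            pool = list(base[season])
            if colony == config.highland_colony and config.highland_pool_divergence > 0:
                n_repl = round(config.highland_pool_divergence * len(pool))
                if n_repl:
                    idx = rng.choice(len(pool), size=n_repl, replace=False)
                    private = _new_species(counter, n_repl)
                    for k, i in enumerate(sorted(idx)):
                        pool[i] = private[k]
            pools[(colony, season)] = pool

    all_species = sorted({sp for pool in pools.values() for sp in pool})
    taxonomy = _assign_taxonomy(all_species, config)

    wrng = _rng(config.rng_seed, "abundance")
    abundance: dict[str, dict[str, float]] = {s: {} for s in seasons}
    for season in seasons:
        members = sorted({sp for c in config.colonies for sp in pools[(c, season)]})
        draws = np.exp(wrng.normal(0.0, config.abundance_sigma, size=len(members)))
        abundance[season] = dict(zip(members, draws))

    srng = _rng(config.rng_seed, "size_factors")
    size_factors = {
        sp: float(np.exp(srng.normal(0.0, config.biomass_sigma))) for sp in all_species
    }
    brng = _rng(config.rng_seed, "bias")
    bias_factors = {
        sp: float(np.exp(brng.normal(0.0, config.bias_sigma))) for sp in all_species
    }
    return pools, taxonomy, abundance, size_factors, bias_factors


def _assign_taxonomy(species: list[str], config: SyntheticConfig) -> dict[str, TaxonRecord]:
    rng = _rng(config.rng_seed, "taxonomy")
    weights = np.array([w for *_, w in FAMILY_CATALOGUE])
    weights = weights / weights.sum()
    idx = rng.choice(len(FAMILY_CATALOGUE), size=len(species), p=weights)
    out = {}
    for sp, i in zip(species, idx):
        class_, order, family, _ = FAMILY_CATALOGUE[i]
        out[sp] = TaxonRecord(
            motu_id=sp,
            class_=class_,
            order=order,
            family=family,
            genus=f"{family[:-2]}us",
            species=f"{family[:-2]}us {sp}",
            match_similarity=float(np.round(98.0 + 2.0 * rng.random(), 2)),
        )
    return out


def _zt_negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Zero-truncated negative binomial draw (rejection sampling)."""
    p = dispersion / (dispersion + mean)
    for _ in range(1000):
        k = int(rng.negative_binomial(dispersion, p))
        if k > 0:
            return k
    return 1


def sample_pellets(
    pool: list[str],
    weights: dict[str, float],
    config: SyntheticConfig,
    n_pellets: int,
    rng: np.random.Generator,
    size_factors: dict[str, float] | None = None,
):
    """Draw the prey content of one pooled sample.

    Each pellet contains a zero-truncated negative-binomial number of
    prey individuals drawn (with replacement) from the pool with
    abundance weights; the sample is the union of its pellets. True diet
    proportions are biomass-weighted: count x per-species size factor,
    normalized.
    """
    if n_pellets < 1:
        raise ValueError("need at least one pellet")
    if not pool:
        raise ValueError("empty prey pool")
    w = np.array([weights.get(sp, 1.0) for sp in pool], dtype=float)
    w = w / w.sum()
    counts: dict[str, int] = {}
    for _ in range(n_pellets):
        k = _zt_negbin(rng, config.prey_per_pellet, config.prey_per_pellet_dispersion)
        for i in rng.choice(len(pool), size=k, p=w, replace=True):
            counts[pool[i]] = counts.get(pool[i], 0) + 1
    sf = size_factors or {}
    biomass = {sp: c * sf.get(sp, 1.0) for sp, c in counts.items()}
    total = sum(biomass.values())
    proportions = {sp: b / total for sp, b in biomass.items()}
    return counts, proportions


def simulate_reads(
    proportions: dict[str, float],
    bias_factors: dict[str, float],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Multinomial read counts with expected share prop x bias."""
    species = sorted(proportions)
    p = np.array([proportions[sp] * bias_factors.get(sp, 1.0) for sp in species])
    if not np.isclose(sum(proportions.values()), 1.0, atol=1e-6):
        raise ValueError("true proportions must sum to 1")
    p = p / p.sum()
    draws = rng.multinomial(config.reads_per_sample, p)
    return {sp: int(c) for sp, c in zip(species, draws) if c > 0}


def inject_artifacts(
    counts: pd.DataFrame, config: SyntheticConfig, rng: np.random.Generator
):
    """Add error MOTUs, contaminant MOTUs and blank samples.

    Error MOTUs appear in a single sample with 1-4 reads (below the
    global 5-read filter). Contaminant MOTUs carry reads in every blank
    and in a random subset of real samples. Blanks contain nothing but
    contaminants. Returns (augmented table, artifact labels).
    """
    labels = {m: "genuine" for m in counts.columns}
    table = counts.copy()
    err_cols: dict[str, pd.Series] = {}
    n_err_total = 0
    for sample in table.index:
        for _ in range(rng.poisson(config.singleton_error_rate)):
            n_err_total += 1
            name = f"err{n_err_total:04d}"
            col = pd.Series(0, index=table.index)
            col[sample] = int(rng.integers(1, 5))
            err_cols[name] = col
            labels[name] = "error"
    cont_cols: dict[str, pd.Series] = {}
    blank_ids = [f"blank{i + 1}" for i in range(config.n_blanks)]
    for i in range(config.contaminant_motus):
        name = f"cont{i + 1:02d}"
        col = pd.Series(0, index=list(table.index) + blank_ids)
        for b in blank_ids:
            col[b] = int(rng.integers(50, 500))
        for sample in table.index:
            if rng.random() < 0.3:
                col[sample] = int(rng.integers(20, 200))
        cont_cols[name] = col
        labels[name] = "contaminant"
    out = table.reindex(index=list(table.index) + blank_ids, fill_value=0)
    if err_cols:
        out = pd.concat(
            [out, pd.DataFrame(err_cols).reindex(out.index, fill_value=0)], axis=1
        )
    if cont_cols:
        out = pd.concat([out, pd.DataFrame(cont_cols)], axis=1)
    return out.fillna(0).astype(int), labels, blank_ids


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Full synthetic dataset: MOTU table, taxonomy, metadata, truth."""
    if config is None:
        config = SyntheticConfig()
    pools, taxonomy, abundance, size_factors, bias_factors = build_species_pools(config)

    rows: dict[str, dict[str, int]] = {}
    meta_rows = []
    diet_proportions: dict[str, dict[str, float]] = {}
    small_colony = config.colonies[0]

    for colony in config.colonies:
        for date_idx, season in enumerate(config.season_of_date, start=1):
            pool = pools[(colony, season)]
            drng = _rng(config.rng_seed, f"date|{colony}|{date_idx}")
            n_avail = max(1, round(config.date_availability * len(pool)))
            date_pool = [pool[i] for i in sorted(drng.choice(len(pool), n_avail, replace=False))]

            units = [("community", None)]
            if colony == small_colony:
                units += [("small", j + 1) for j in range(config.n_small_replicates)]
            for regime, rep in units:
                if regime == "community":
                    sid = f"{colony}_d{date_idx:02d}_comm"
                    prng = _rng(config.rng_seed, f"sample|{sid}")
                    lo, hi = config.pellets_per_community
                    n_pellets = int(prng.integers(lo, hi + 1))
                else:
                    sid = f"{colony}_d{date_idx:02d}_rep{rep}"
                    prng = _rng(config.rng_seed, f"sample|{sid}")
                    n_pellets = config.pellets_per_small
                _, props = sample_pellets(
                    date_pool, abundance[season], config, n_pellets, prng, size_factors
                )
                reads = simulate_reads(props, bias_factors, config, prng)
                rows[sid] = reads
                diet_proportions[sid] = props
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "colony": colony,
                        "date_index": date_idx,
                        "season": season,
                        "regime": regime,
                        "pellet_count": n_pellets,
                    }
                )

    all_species = sorted({sp for r in rows.values() for sp in r})
    counts = pd.DataFrame(
        [[rows[sid].get(sp, 0) for sp in all_species] for sid in rows],
        index=list(rows),
        columns=all_species,
        dtype=int,
    )
    arng = _rng(config.rng_seed, "artifacts")
    augmented, labels, blank_ids = inject_artifacts(counts, config, arng)
    for b in blank_ids:
        meta_rows.append(
            {
                "sample_id": b,
                "colony": "",
                "date_index": 0,
                "season": "",
                "regime": "blank",
                "pellet_count": 0,
            }
        )
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")

    crng = _rng(config.rng_seed, "contaminant_taxonomy")
    taxonomy = dict(taxonomy)
    for motu, lab in labels.items():
        if lab == "contaminant":
            taxonomy[motu] = TaxonRecord(
                motu_id=motu,
                class_="Mammalia",
                order="Primates",
                family="Hominidae",
                genus="Homo",
                species="Homo sapiens",
                match_similarity=float(np.round(99.0 + crng.random(), 2)),
            )

    truth = SyntheticTruth(
        species_pools=pools,
        abundance_weights=abundance,
        diet_proportions=diet_proportions,
        bias_factors=bias_factors,
        size_factors=size_factors,
        artifact_labels=labels,
    )
    return SyntheticDataset(
        table=MotuTable(counts=augmented),
        taxonomy=taxonomy,
        metadata=metadata,
        truth=truth,
    )


_BASES = np.array(list("ACGT"))


def random_amplicon(rng: np.random.Generator, length: int = 157) -> str:
    """Random DNA template of the target amplicon length."""
    return "".join(rng.choice(_BASES, size=length))


def simulate_read_pairs(
    template: str,
    n_pairs: int,
    rng: np.random.Generator,
    read_len: int = 150,
    substitution_rate: float = 0.0,
    quality: int = 38,
    id_prefix: str = "read",
) -> list[tuple[SequenceRead, SequenceRead]]:
    """Paired 150-bp reads off a template; errors are single substitutions.

    The forward read covers the template prefix, the reverse read the
    reverse complement of the suffix; per-base substitutions occur at
    ``substitution_rate`` with a reduced quality score at the error site.
    """
    if len(template) < read_len:
        read_len = len(template)
    pairs = []
    comp = str.maketrans("ACGTN", "TGCAN")
    for i in range(n_pairs):
        fwd_bases = list(template[:read_len])
        rev_bases = list(template[-read_len:].translate(comp)[::-1])
        fq = [quality] * read_len
        rq = [quality] * read_len
        for bases, quals in ((fwd_bases, fq), (rev_bases, rq)):
            for j in range(read_len):
                if rng.random() < substitution_rate:
                    alternatives = [b for b in "ACGT" if b != bases[j]]
                    bases[j] = alternatives[int(rng.integers(3))]
                    quals[j] = max(2, quality - 20)
        pairs.append(
            (
                SequenceRead(f"{id_prefix}{i + 1}/1", "".join(fwd_bases), tuple(fq)),
                SequenceRead(f"{id_prefix}{i + 1}/2", "".join(rev_bases), tuple(rq)),
            )
        )
    return pairs
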