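import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from guanodiet import datasets, niche, ordination, read_pipeline as rp, synthetic


@pytest.fixture
def small_counts():
    """3 samples x 3 MOTUs with a zero column pattern exercised in filters."""
    return pd.DataFrame(
        [[0, 7, 1], [5, 0, 2], [3, 3, 0]],
        index=["s1", "s2", "s3"],
        columns=["m1", "m2", "m3"],
    )


def _clean_community(ds):
    cleaned, _, _ = rp.run_table_pipeline(
        ds.table, ds.taxonomy, blank_sample_ids=ds.blank_ids
    )
    meta = ds.metadata.loc[cleaned.sample_ids]
    comm_ids = list(meta.index[meta["regime"] == "community"])
    small_ids = list(meta.index[meta["regime"] == "small"])
    comm = rp.MotuTable(counts=cleaned.counts.loc[comm_ids]).drop_empty_motus()
    small = rp.MotuTable(counts=cleaned.counts.loc[small_ids]).drop_empty_motus()
    return comm, small, meta.loc[comm_ids]


def _true_overlap(ds, comm_ids, meta_c):
    """Morisita-Horn overlap of colony x season pools of the TRUE diet."""
    props = ds.truth.diet_proportions
    species = sorted({sp for sid in comm_ids for sp in props[sid]})
    mat = pd.DataFrame(
        [[props[sid].get(sp, 0.0) for sp in species] for sid in comm_ids],
        index=comm_ids,
        columns=species,
    )
    pools = mat.groupby(
        [meta_c["colony"].values, meta_c["season"].values]
    ).mean()
    pools.index = [f"{c}|{s}" for c, s in pools.index]
    return niche.overlap_matrix(pools)


def end_to_end_stats(seed: int, bias_sigma: float | None = None) -> dict:
    """One full synthetic run reduced to the recovery statistics under test."""
    kwargs = {} if bias_sigma is None else {"bias_sigma": bias_sigma}
    ds = synthetic.generate_dataset(synthetic.SyntheticConfig(rng_seed=seed, **kwargs))
    comm, small, meta_c = _clean_community(ds)

    occ = datasets.to_occurrence(comm)
    rich = occ.richness()
    occ_small = datasets.to_occurrence(small)

    season_means = rich.groupby(meta_c["season"]).mean().to_dict()

    pools_w = niche.pool_by_season(comm.counts, meta_c, treatment="wpoo")
    ov = niche.overlap_matrix(pools_w)
    seasons = [u.split("|")[1] for u in ov.index]
    colonies = [u.split("|")[0] for u in ov.index]
    highland = synthetic.SyntheticConfig().highland_colony
    within, spring_autumn, hl_within, ll_within = [], [], [], []
    for i, j in itertools.combinations(range(len(ov)), 2):
        v = ov.iloc[i, j]
        if seasons[i] == seasons[j]:
            within.append(v)
            if highland in (colonies[i], colonies[j]):
                hl_within.append(v)
            else:
                ll_within.append(v)
        elif {seasons[i], seasons[j]} == {"spring", "autumn"}:
            spring_autumn.append(v)

    res_w = ordination.pcoa(ordination.similarity_to_distance(ov))
    sep_season_w = ordination.group_separation(res_w, seasons)
    labels_hl = ["highland" if c == highland else "lowland" for c in colonies]
    sep_highland = ordination.group_separation(res_w, labels_hl)

    pools_r = niche.pool_by_season(comm.counts, meta_c, treatment="rra")
    ov_r = niche.overlap_matrix(pools_r)
    res_r = ordination.pcoa(ordination.similarity_to_distance(ov_r))
    sep_season_r = ordination.group_separation(res_r, seasons)

    # rank agreement of estimated pool overlaps with the true-diet overlaps
    ov_true = _true_overlap(ds, list(comm.counts.index), meta_c)
    shared = [u for u in ov_true.index if u in ov.index]
    truth_vals = ov_true.loc[shared, shared].to_numpy()[np.triu_indices(len(shared), 1)]
    wpoo_vals = ov.loc[shared, shared].to_numpy()[np.triu_indices(len(shared), 1)]
    rra_vals = ov_r.loc[shared, shared].to_numpy()[np.triu_indices(len(shared), 1)]
    corr_wpoo = float(sps.spearmanr(truth_vals, wpoo_vals).statistic)
    corr_rra = float(sps.spearmanr(truth_vals, rra_vals).statistic)

    norare, _ = datasets.drop_rare_items(occ)
    loss = (rich - norare.richness()).to_numpy(dtype=float)
    if np.ptp(loss) > 0 and np.ptp(rich.to_numpy()) > 0:
        rank_corr = float(sps.spearmanr(rich.to_numpy(), loss).statistic)
    else:
        rank_corr = float("nan")

    return {
        "mean_richness_community": float(rich.mean()),
        "mean_richness_small": float(occ_small.richness().mean()),
        "season_mean_richness": season_means,
        "within_season_overlap": float(np.mean(within)),
        "spring_autumn_overlap": float(np.mean(spring_autumn)),
        "highland_within_overlap": float(np.mean(hl_within)),
        "lowland_within_overlap": float(np.mean(ll_within)),
        "season_sep_axes12_wpoo": sep_season_w.get("axes_1-2", float("nan")),
        "season_sep_axes12_rra": sep_season_r.get("axes_1-2", float("nan")),
        "highland_sep_axes12": sep_highland.get("axes_1-2", float("nan")),
        "highland_sep_axis3": sep_highland.get("axes_3", float("nan")),
        "richness_breadth_loss_rank_corr": rank_corr,
        "truth_overlap_corr_wpoo": corr_wpoo,
        "truth_overlap_corr_rra": corr_rra,
    }


N_RECOVERY_SEEDS = 20


@pytest.fixture(scope="session")
def multiseed_stats():
    """Default-config end-to-end statistics over the recovery seeds."""
    return [end_to_end_stats(seed) for seed in range(N_RECOVERY_SEEDS)]


@pytest.fixture(scope="session")
def multiseed_stats_high_bias():
    """Same runs with amplification bias strong enough to degrade RRA."""
    return [end_to_end_stats(seed, bias_sigma=2.9) for seed in range(N_RECOVERY_SEEDS)]
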