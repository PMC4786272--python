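"""Synthetic integrative studies with planted ground truth.

Generates everything the downstream pipeline consumes — a negative-
binomial count matrix, dye-swap two-color spot tables with dye bias and
intensity-dependent print-tip trends, a single-channel log2 expression
matrix, a target-annotation table mixing true targets with decoys, and
gene-set collections — from a single :class:`SimulationConfig`, together
with the planted truth (which features are differentially expressed and
which miRNA-mRNA pairs are truly coupled).

Study design emulated: two groups (MSA-like transgenic vs control),
a small number of pooled biological replicates per group that are shared
across platforms (the same pool is measured by sequencing and by both
array platforms), balanced dye-swap pairs for the two-color arrays, and
negative coupling of each true target's latent expression to its
regulator miRNA's latent expression.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .arrays import TwoColorArraySet
from .rnaseq import CountMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "simulate_rnaseq_counts",
    "simulate_dyeswap_arrays",
    "simulate_target_annotations",
    "make_gene_sets",
    "generate_study",
    "write_study",
    "read_study",
]

PROGRAM_COLS = ("pred_mirwalk", "pred_rna22", "pred_miranda", "pred_targetscan")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic region.

    Defaults mirror the emulated design: 2000 genes, 300 miRNA probes,
    3 pooled replicates per group, 5% differential features at |log2FC|
    = 2, NB dispersion 0.05, 40 truly coupled miRNA-mRNA interactions
    with coupling strength 0.8, a 0.5 log2 dye bias, 8 print-tip groups
    with a 0.3 log2 intensity-dependent trend, duplicate spots in pairs,
    and a 2% rate at which random candidate pairs carry qualifying
    (decoy) target-prediction evidence.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    n_samples_per_group: int = 3
    baseline_mean_log_range: tuple[float, float] = (3.0, 10.0)
    dispersion_alpha: float = 0.05
    frac_de: float = 0.05
    log2fc_magnitude: float = 2.0
    n_true_interactions: int = 40
    coupling_strength: float = 0.8
    dye_bias: float = 0.5
    n_printtips: int = 8
    trend_amplitude: float = 0.3
    decoy_annotation_rate: float = 0.02
    duplicates_per_probe: int = 2
    pool_noise_sd: float = 0.25
    spot_noise_sd: float = 0.1
    mrna_array_noise_sd: float = 0.15
    background_level: float = 50.0
    frac_unannotated: float = 0.05
    region: str = "striatum"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_mirnas", "n_samples_per_group", "n_printtips", "duplicates_per_probe"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or isinstance(v, bool) or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("frac_de", "decoy_annotation_rate", "coupling_strength", "frac_unannotated"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if not self.dispersion_alpha >= 0:
            raise ValueError("dispersion_alpha must be non-negative")
        if not self.log2fc_magnitude > 0:
            raise ValueError("log2fc_magnitude must be positive")
        if self.n_true_interactions < 0 or not isinstance(self.n_true_interactions, numbers.Integral):
            raise ValueError("n_true_interactions must be a non-negative integer")
        lo, hi = self.baseline_mean_log_range
        if not lo <= hi:
            raise ValueError("baseline_mean_log_range must be an interval (lo <= hi)")
        if not isinstance(self.seed, numbers.Integral):
            raise ValueError("seed must be an integer")


@dataclass
class SyntheticTruth:
    """Planted ground truth: signed DE features and true interactions."""

    de_mrnas: dict[str, float] = field(default_factory=dict)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    true_interactions: set[tuple[str, str]] = field(default_factory=set)

    def validate(self) -> None:
        for mir, gene in self.true_interactions:
            if mir not in self.de_mirnas or gene not in self.de_mrnas:
                raise ValueError(f"interaction ({mir}, {gene}) references a non-DE feature")
            if np.sign(self.de_mirnas[mir]) == np.sign(self.de_mrnas[gene]):
                raise ValueError(f"interaction ({mir}, {gene}) has same-sign fold changes")


@dataclass
class SyntheticStudy:
    """Bundle of all synthetic inputs plus the planted truth."""

    counts: CountMatrix
    arrays: TwoColorArraySet
    mrna_log2: pd.DataFrame
    annotations: pd.DataFrame
    gene_sets: dict[str, set]
    truth: SyntheticTruth
    sample_map: pd.DataFrame
    config: SimulationConfig


def _gene_ids(n: int) -> list[str]:
    return [f"gene{str(i + 1).zfill(4)}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"mmu-miR-{str(i + 1).zfill(4)}" for i in range(n)]


def _sample_names(n_per_group: int) -> list[str]:
    return [f"CTL_P{i + 1}" for i in range(n_per_group)] + [f"MSA_P{i + 1}" for i in range(n_per_group)]


def _group_indicator(n_per_group: int) -> np.ndarray:
    return np.array([0] * n_per_group + [1] * n_per_group)


def _plant_de(rng: np.random.Generator, ids: list[str], frac_de: float, magnitude: float) -> dict[str, float]:
    """Pick round(frac_de * n) features and give them balanced +/- effects."""
    n_de = int(round(frac_de * len(ids)))
    chosen = rng.choice(len(ids), size=n_de, replace=False)
    signs = np.ones(n_de)
    signs[1::2] = -1.0
    return {ids[int(i)]: float(s * magnitude) for i, s in zip(chosen, signs)}


def _sample_meta(n_per_group: int, region: str) -> pd.DataFrame:
    names = _sample_names(n_per_group)
    return pd.DataFrame(
        {
            "group": ["control"] * n_per_group + ["MSA"] * n_per_group,
            "pool": [f"P{i + 1}" for i in range(n_per_group)] * 2,
            "region": region,
        },
        index=pd.Index(names, name="sample"),
    )


def _counts_from_latent(
    rng: np.random.Generator, latent_log2: pd.DataFrame, alpha: float
) -> tuple[pd.DataFrame, np.ndarray]:
    """NB(mean = sf_j * 2^latent, dispersion alpha) counts via gamma-Poisson."""
    n_samples = latent_log2.shape[1]
    sf = rng.uniform(0.7, 1.4, n_samples)
    sf = sf / np.exp(np.mean(np.log(sf)))
    mu = sf[None, :] * np.power(2.0, latent_log2.to_numpy())
    if alpha <= 1e-12:
        y = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
        y = rng.poisson(lam)
    return pd.DataFrame(y, index=latent_log2.index, columns=latent_log2.columns), sf


def simulate_rnaseq_counts(config: SimulationConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Two-group NB count matrix with planted differential genes.

    Counts are NB(mean = sf_j * 2^(b_g + beta_g*x_j + e_gj), dispersion
    alpha) where x_j is the group indicator, exactly round(frac_de *
    n_genes) genes carry beta_g = +/- log2fc_magnitude with balanced
    signs, and e_gj is an optional pool-level biological effect
    (sd ``pool_noise_sd`` in log2 units; set it to 0 for the pure NB
    model). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = _gene_ids(config.n_genes)
    de = _plant_de(rng, genes, config.frac_de, config.log2fc_magnitude)
    lo, hi = config.baseline_mean_log_range
    b = rng.uniform(lo, hi, config.n_genes)
    beta = np.array([de.get(g, 0.0) for g in genes])
    x = _group_indicator(config.n_samples_per_group)
    samples = _sample_names(config.n_samples_per_group)
    latent = b[:, None] + beta[:, None] * x[None, :]
    if config.pool_noise_sd > 0:
        latent = latent + rng.normal(0.0, config.pool_noise_sd, latent.shape)
    latent = pd.DataFrame(latent, index=pd.Index(genes, name="gene_id"), columns=samples)
    counts, _ = _counts_from_latent(rng, latent, config.dispersion_alpha)
    cm = CountMatrix(counts, _sample_meta(config.n_samples_per_group, config.region))
    return cm, SyntheticTruth(de_mrnas=de)


def _mirna_latent(
    rng: np.random.Generator, config: SimulationConfig, de: dict[str, float], mirnas: list[str]
) -> pd.DataFrame:
    lo, hi = config.baseline_mean_log_range
    b = rng.uniform(lo, hi, len(mirnas))
    beta = np.array([de.get(m, 0.0) for m in mirnas])
    x = _group_indicator(config.n_samples_per_group)
    latent = b[:, None] + beta[:, None] * x[None, :]
    if config.pool_noise_sd > 0:
        latent = latent + rng.normal(0.0, config.pool_noise_sd, latent.shape)
    return pd.DataFrame(
        latent, index=pd.Index(mirnas, name="probe_id"), columns=_sample_names(config.n_samples_per_group)
    )


def _probe_annotation(rng: np.random.Generator, config: SimulationConfig, mirnas: list[str]) -> pd.DataFrame:
    species = np.where(rng.random(len(mirnas)) < config.frac_unannotated, "other", "mouse")
    return pd.DataFrame({"species": species}, index=pd.Index(mirnas, name="probe_id"))


def _arrays_from_latent(
    rng: np.random.Generator,
    latent: pd.DataFrame,
    config: SimulationConfig,
    probe_annotation: pd.DataFrame,
) -> TwoColorArraySet:
    """Dye-swap spot tables from a per-sample latent log2 matrix.

    One dye-swap pair (two arrays with opposite orientation) per pooled
    replicate. Per spot, channel log2 signal = latent(sample) +/-
    dye_bias/2 +/- trend(A)/2 + noise; foreground = 2^signal + recorded
    local background, so plain background subtraction recovers the
    signal exactly.
    """
    probes = list(latent.index)
    n_spots = len(probes) * config.duplicates_per_probe
    spot_probe = np.repeat(np.arange(len(probes)), config.duplicates_per_probe)
    printtip = (np.arange(n_spots) * config.n_printtips) // n_spots + 1
    lo, hi = config.baseline_mean_log_range
    mid, half = (lo + hi) / 2.0, max((hi - lo) / 2.0, 1e-9)

    tables: dict[str, pd.DataFrame] = {}
    meta_rows = []
    L = latent.to_numpy()
    for r in range(config.n_samples_per_group):
        pool = f"P{r + 1}"
        ctl_col, msa_col = r, config.n_samples_per_group + r
        tip_coef = rng.uniform(0.5, 1.0, config.n_printtips) * config.trend_amplitude
        for orientation in ("MSA_in_red", "MSA_in_green"):
            aid = f"{config.region}_{pool}_{'rg' if orientation == 'MSA_in_red' else 'gr'}"
            red_col = msa_col if orientation == "MSA_in_red" else ctl_col
            green_col = ctl_col if orientation == "MSA_in_red" else msa_col
            lat_r = L[spot_probe, red_col]
            lat_g = L[spot_probe, green_col]
            a_true = (lat_r + lat_g) / 2.0
            trend = tip_coef[printtip - 1] * (((a_true - mid) / half) ** 2 - 1.0 / 3.0)
            noise_r = rng.normal(0.0, config.spot_noise_sd, n_spots) if config.spot_noise_sd > 0 else 0.0
            noise_g = rng.normal(0.0, config.spot_noise_sd, n_spots) if config.spot_noise_sd > 0 else 0.0
            sig_r = lat_r + config.dye_bias / 2.0 + trend / 2.0 + noise_r
            sig_g = lat_g - config.dye_bias / 2.0 - trend / 2.0 + noise_g
            bg_r = config.background_level * rng.uniform(0.9, 1.1, n_spots)
            bg_g = config.background_level * rng.uniform(0.9, 1.1, n_spots)
            tables[aid] = pd.DataFrame(
                {
                    "probe_id": [probes[i] for i in spot_probe],
                    "printtip": printtip,
                    "fg_r": np.power(2.0, sig_r) + bg_r,
                    "bg_r": bg_r,
                    "fg_g": np.power(2.0, sig_g) + bg_g,
                    "bg_g": bg_g,
                }
            )
            meta_rows.append({"array_id": aid, "orientation": orientation, "pool": pool, "region": config.region})
    meta = pd.DataFrame(meta_rows).set_index("array_id")
    return TwoColorArraySet(tables, meta, probe_annotation)


def simulate_dyeswap_arrays(config: SimulationConfig) -> tuple[TwoColorArraySet, SyntheticTruth]:
    """Dye-swap two-color array set with planted miRNA differences."""
    rng = np.random.default_rng([config.seed, 2])
    mirnas = _mirna_ids(config.n_mirnas)
    annotation = _probe_annotation(rng, config, mirnas)
    mouse = [m for m in mirnas if annotation.loc[m, "species"] == "mouse"]
    de = _plant_de(rng, mouse, config.frac_de * len(mirnas) / max(len(mouse), 1), config.log2fc_magnitude)
    latent = _mirna_latent(rng, config, de, mirnas)
    arrays = _arrays_from_latent(rng, latent, config, annotation)
    return arrays, SyntheticTruth(de_mirnas=de)


def _draw_evidence(rng: np.random.Generator, force_qualify: bool) -> dict:
    """One annotation row's evidence fields; optionally force a clause."""
    validated = bool(rng.random() < 0.25)
    p = float(rng.uniform(0.0, 0.1)) if rng.random() < 0.7 else float(rng.uniform(0.1, 1.0))
    flags = rng.random(4) < 0.4
    if force_qualify and not (p < 0.1 or flags.sum() >= 2 or validated):
        p = float(rng.uniform(0.0, 0.1))
    return {
        "mirwalk_p": p,
        **{c: bool(f) for c, f in zip(PROGRAM_COLS, flags)},
        "validated": validated,
    }


def simulate_target_annotations(
    truth: SyntheticTruth,
    config: SimulationConfig,
    gene_ids=None,
    mirna_ids=None,
) -> pd.DataFrame:
    """Target-annotation table mixing true targets with decoys.

    Every true interaction gets a row carrying at least one qualifying
    evidence clause (mirwalk p < 0.1, or >= 2 program predictions, or a
    validated flag). Decoy pairs — the non-true combinations of planted
    DE miRNAs and DE mRNAs — receive a qualifying row with probability
    ``decoy_annotation_rate``, and a non-qualifying noise row (a single
    program flag, large p, not validated) at the same rate.
    """
    if not truth.de_mirnas and truth.true_interactions:
        raise ValueError("truth has interactions but no DE miRNAs")
    if gene_ids is not None:
        unknown = set(g for _, g in truth.true_interactions) - set(gene_ids)
        unknown |= set(truth.de_mrnas) - set(gene_ids)
        if unknown:
            raise ValueError(f"truth references unknown gene ids: {sorted(unknown)[:5]}")
    if mirna_ids is not None:
        unknown = set(m for m, _ in truth.true_interactions) - set(mirna_ids)
        unknown |= set(truth.de_mirnas) - set(mirna_ids)
        if unknown:
            raise ValueError(f"truth references unknown miRNA ids: {sorted(unknown)[:5]}")
    rng = np.random.default_rng([config.seed, 3])
    rows = []
    for mir, gene in sorted(truth.true_interactions):
        rows.append({"mirna_id": mir, "gene_id": gene, **_draw_evidence(rng, force_qualify=True)})
    decoys = [
        (m, g)
        for m in sorted(truth.de_mirnas)
        for g in sorted(truth.de_mrnas)
        if (m, g) not in truth.true_interactions
    ]
    if decoys:
        draw = rng.random(len(decoys))
        for (m, g), u in zip(decoys, draw):
            if u < config.decoy_annotation_rate:
                rows.append({"mirna_id": m, "gene_id": g, **_draw_evidence(rng, force_qualify=True)})
            elif u < 2 * config.decoy_annotation_rate:
                flags = {c: False for c in PROGRAM_COLS}
                flags[PROGRAM_COLS[int(rng.integers(4))]] = True
                rows.append(
                    {
                        "mirna_id": m,
                        "gene_id": g,
                        "mirwalk_p": float(rng.uniform(0.2, 1.0)),
                        **flags,
                        "validated": False,
                    }
                )
    cols = ["mirna_id", "gene_id", "mirwalk_p", *PROGRAM_COLS, "validated"]
    return pd.DataFrame(rows, columns=cols)


def make_gene_sets(
    rng: np.random.Generator,
    gene_ids: list[str],
    de_genes: dict[str, float],
    n_sets: int = 20,
    set_size: int = 30,
) -> dict[str, set]:
    """Random gene sets plus one set enriched in planted DE genes."""
    sets: dict[str, set] = {}
    de_list = sorted(de_genes)
    if de_list:
        n_de_members = min(max(set_size // 2, 2), len(de_list))
        members = set(rng.choice(de_list, n_de_members, replace=False))
        fill = [g for g in gene_ids if g not in members]
        members |= set(rng.choice(fill, max(set_size - n_de_members, 0), replace=False))
        sets["planted_de_set"] = members
    for i in range(n_sets):
        sets[f"random_set_{i + 1:02d}"] = set(rng.choice(gene_ids, set_size, replace=False))
    return sets


def generate_study(config: SimulationConfig, out_dir=None) -> SyntheticStudy:
    """Complete coordinated study with negatively coupled interactions.

    The miRNA latent expression is generated first; each true target
    gene's latent log2 expression is ``baseline - coupling_strength *
    (regulator's latent deviation from its own baseline)``, which plants
    the negative correlation (and an opposite-sign fold change of
    magnitude coupling_strength * log2fc_magnitude). All platforms
    measure the same pooled replicates, so the matrices are
    column-matchable by pool id. When ``out_dir`` is given the study is
    also written as plain-text fixtures (see :func:`write_study`).
    """
    rng = np.random.default_rng([config.seed, 0])
    genes = _gene_ids(config.n_genes)
    mirnas = _mirna_ids(config.n_mirnas)
    samples = _sample_names(config.n_samples_per_group)
    x = _group_indicator(config.n_samples_per_group)

    annotation = _probe_annotation(rng, config, mirnas)
    mouse = [m for m in mirnas if annotation.loc[m, "species"] == "mouse"]
    de_mirnas = _plant_de(rng, mouse, config.frac_de * len(mirnas) / max(len(mouse), 1), config.log2fc_magnitude)

    n_de_genes = int(round(config.frac_de * config.n_genes))
    if config.n_true_interactions > n_de_genes:
        raise ValueError("n_true_interactions cannot exceed the number of DE genes")
    de_gene_ids = [genes[int(i)] for i in rng.choice(config.n_genes, n_de_genes, replace=False)]

    interactions: set[tuple[str, str]] = set()
    regulators = sorted(de_mirnas)
    target_genes = de_gene_ids[: config.n_true_interactions] if regulators else []
    for i, g in enumerate(target_genes):
        interactions.add((regulators[i % len(regulators)], g))

    de_mrnas: dict[str, float] = {}
    target_of = {g: m for m, g in interactions}
    signs = np.ones(n_de_genes)
    signs[1::2] = -1.0
    for i, g in enumerate(de_gene_ids):
        if g in target_of:
            de_mrnas[g] = -config.coupling_strength * de_mirnas[target_of[g]]
        else:
            de_mrnas[g] = float(signs[i] * config.log2fc_magnitude)

    truth = SyntheticTruth(de_mrnas=de_mrnas, de_mirnas=de_mirnas, true_interactions=interactions)
    truth.validate()

    mirna_latent = _mirna_latent(rng, config, de_mirnas, mirnas)
    lo, hi = config.baseline_mean_log_range
    b_g = rng.uniform(lo, hi, config.n_genes)
    beta_g = np.array([de_mrnas.get(g, 0.0) for g in genes])
    gene_latent = b_g[:, None] + beta_g[:, None] * x[None, :]
    if config.pool_noise_sd > 0:
        gene_latent = gene_latent + rng.normal(0.0, config.pool_noise_sd, gene_latent.shape)
    gene_latent = pd.DataFrame(gene_latent, index=pd.Index(genes, name="gene_id"), columns=samples)
    # couple targets to their regulator's latent deviation (pool effects included)
    for mir, gene in interactions:
        i = mirnas.index(mir)
        dev = mirna_latent.iloc[i].to_numpy() - (mirna_latent.iloc[i, : config.n_samples_per_group].mean())
        own = rng.normal(0.0, config.pool_noise_sd * 0.5, len(samples)) if config.pool_noise_sd > 0 else 0.0
        gi = genes.index(gene)
        gene_latent.iloc[gi] = b_g[gi] - config.coupling_strength * dev + own

    counts_df, _ = _counts_from_latent(rng, gene_latent, config.dispersion_alpha)
    counts = CountMatrix(counts_df, _sample_meta(config.n_samples_per_group, config.region))
    arrays = _arrays_from_latent(rng, mirna_latent, config, annotation)
    mrna_log2 = gene_latent + rng.normal(0.0, config.mrna_array_noise_sd, gene_latent.shape)
    annotations = simulate_target_annotations(truth, config, gene_ids=genes, mirna_ids=mirnas)
    gene_sets = make_gene_sets(rng, genes, de_mrnas)
    sample_map = pd.DataFrame(
        {
            "pool": [f"P{i + 1}" for i in range(config.n_samples_per_group)] * 2,
            "mirna_sample": samples,
            "mrna_sample": samples,
        }
    )
    study = SyntheticStudy(counts, arrays, mrna_log2, annotations, gene_sets, truth, sample_map, config)
    if out_dir is not None:
        write_study(study, out_dir)
    return study


# ---------------------------------------------------------------------------
# plain-text fixture IO

def write_study(study: SyntheticStudy, out_dir) -> None:
    """Write all study components as TSV/GMT fixtures under ``out_dir``."""
    from .enrich import write_gmt

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        (out / "arrays").mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc
    study.counts.values.to_csv(out / "counts.tsv", sep="\t")
    study.counts.samples.to_csv(out / "samples.tsv", sep="\t")
    for aid, tab in study.arrays.arrays.items():
        tab.to_csv(out / "arrays" / f"{aid}.tsv", sep="\t", index=False)
    study.arrays.meta.to_csv(out / "arrays_meta.tsv", sep="\t")
    study.arrays.probe_annotation.to_csv(out / "probe_annotation.tsv", sep="\t")
    study.mrna_log2.to_csv(out / "mrna_log2.tsv", sep="\t")
    study.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    write_gmt(study.gene_sets, out / "sets.gmt")
    study.sample_map.to_csv(out / "sample_map.tsv", sep="\t", index=False)
    pd.Series(study.truth.de_mrnas, name="log2fc").rename_axis("gene_id").to_csv(
        out / "truth_de_mrnas.tsv", sep="\t"
    )
    pd.Series(study.truth.de_mirnas, name="log2fc").rename_axis("mirna_id").to_csv(
        out / "truth_de_mirnas.tsv", sep="\t"
    )
    pd.DataFrame(sorted(study.truth.true_interactions), columns=["mirna_id", "gene_id"]).to_csv(
        out / "truth_interactions.tsv", sep="\t", index=False
    )
    cfg = pd.Series(asdict(study.config)).astype(str)
    cfg.to_csv(out / "config.tsv", sep="\t", header=False)


def read_study(in_dir) -> SyntheticStudy:
    """Read back a study written by :func:`write_study`."""
    from .enrich import read_gmt

    d = Path(in_dir)
    rt = dict(sep="\t", float_precision="round_trip")
    counts = CountMatrix(
        pd.read_csv(d / "counts.tsv", index_col=0, **rt),
        pd.read_csv(d / "samples.tsv", index_col=0, **rt),
    )
    meta = pd.read_csv(d / "arrays_meta.tsv", index_col=0, **rt)
    tables = {
        aid: pd.read_csv(d / "arrays" / f"{aid}.tsv", **rt) for aid in meta.index
    }
    annotation = pd.read_csv(d / "probe_annotation.tsv", index_col=0, **rt)
    arrays = TwoColorArraySet(tables, meta, annotation)
    mrna_log2 = pd.read_csv(d / "mrna_log2.tsv", index_col=0, **rt)
    annotations = pd.read_csv(d / "annotations.tsv", **rt)
    for c in PROGRAM_COLS + ("validated",):
        annotations[c] = annotations[c].astype(bool)
    gene_sets = read_gmt(d / "sets.gmt")
    sample_map = pd.read_csv(d / "sample_map.tsv", **rt)
    de_mrnas = pd.read_csv(d / "truth_de_mrnas.tsv", index_col=0, **rt)["log2fc"].to_dict()
    de_mirnas = pd.read_csv(d / "truth_de_mirnas.tsv", index_col=0, **rt)["log2fc"].to_dict()
    inter_df = pd.read_csv(d / "truth_interactions.tsv", **rt)
    interactions = set(map(tuple, inter_df.to_numpy())) if len(inter_df) else set()
    truth = SyntheticTruth(de_mrnas, de_mirnas, interactions)
    cfg_raw = pd.read_csv(d / "config.tsv", sep="\t", header=None, index_col=0)[1]
    config = _config_from_strings(cfg_raw.to_dict())
    return SyntheticStudy(counts, arrays, mrna_log2, annotations, gene_sets, truth, sample_map, config)


def _config_from_strings(raw: dict[str, str]) -> SimulationConfig:
    import ast

    kwargs = {}
    for f in SimulationConfig.__dataclass_fields__.values():
        if f.name not in raw:
            continue
        v = raw[f.name]
        kwargs[f.name] = v if f.name == "region" else ast.literal_eval(v)
    return SimulationConfig(**kwargs)
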