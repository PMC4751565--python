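"""Synthetic data generator for the full Al-tolerance QTL pipeline.

Emulates a biparental sorghum RIL study: 90 F7:8 lines genotyped at 344
markers on 10 chromosomes, phenotyped for relative net root growth (RNRG)
in a two-block hydroponic screen and for grain yield in paired field trials
(control vs. high-Al-saturation site, each an incomplete block design with
three replicates and ten incomplete blocks), plus a 2 female x 4 male
factorial of isogenic hybrids grown in a split-plot trial.

Two pleiotropic QTL are simulated by default — chromosome 3 at 184.2 cM and
chromosome 9 at 214.0 cM — with per-trait allele-substitution effects on
the B-parent (SC283-type) coding of (0.71, 0.19, 0.61) and
(0.34, -0.66, -0.36) for (RNRG_log10, Gy_control, Gy_Al).  Polygenic
(co)variances are calibrated so each QTL explains the intended share of
genetic variance and line-mean heritabilities fall in the 0.7-0.9 range,
with genetic variance slightly larger under control than under Al stress.

One global seed fans out deterministically to per-component child seeds, so
any stage can be regenerated in isolation and identical seeds give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genmap import (
    GeneticMap,
    GenotypeMatrix,
    ScanGrid,
    genotype_probabilities,
    ril_recombination_fraction,
)

TRAITS = ("RNRG_log10", "Gy_control", "Gy_Al")

# hybrid factorial: (hybrid, female, male, count of tolerance alleles)
HYBRID_TABLE = (
    ("H1", "ATF13A", "R1", 0),
    ("H2", "ATF14A", "R1", 1),
    ("H3", "ATF13A", "R2", 1),
    ("H4", "ATF14A", "R2", 2),
    ("H5", "ATF13A", "R3", 1),
    ("H6", "ATF14A", "R3", 2),
    ("H7", "ATF13A", "R4", 1),
    ("H8", "ATF14A", "R4", 2),
)

_COMPONENT_IDS = {
    "map": 0, "genotypes": 1, "traits": 2, "field": 3, "hydro": 4, "hybrid": 5,
}


def child_seed(seed: int, component: str) -> np.random.SeedSequence:
    """Deterministic per-component seed derived from the global seed."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(_COMPONENT_IDS[component],))


@dataclass(frozen=True)
class QTLSpec:
    chromosome: str
    position_cM: float
    effects: tuple[float, ...]  # B-parent minus A-parent class difference, per trait


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters; defaults reproduce the emulated trial layout."""

    n_lines: int = 90
    chrom_lengths: tuple[float, ...] = (160, 150, 190, 130, 120, 115, 110, 105, 220, 100)
    n_markers: int = 344
    qtl: tuple[QTLSpec, ...] = (
        QTLSpec("3", 184.2, (0.71, 0.19, 0.61)),
        QTLSpec("9", 214.0, (0.34, -0.66, -0.36)),
    )
    trait_names: tuple[str, ...] = TRAITS
    trait_means: tuple[float, ...] = (1.50, 3.35, 2.35)
    # polygenic SDs solved from the target per-QTL shares of genetic variance
    polygenic_sd: tuple[float, ...] = (0.3110, 0.3742, 0.3483)
    polygenic_corr: tuple[tuple[float, ...], ...] = (
        (1.0, 0.1, 0.3),
        (0.1, 1.0, 0.5),
        (0.3, 0.5, 1.0),
    )
    # line-mean (BLUE-scale) error variances: sigma_e^2 / r per trait
    blue_error_var: tuple[float, ...] = (0.028, 0.0667, 0.0733)
    parent_a: str = "BR007"
    parent_b: str = "SC283"
    # field design (per environment)
    n_replicates: int = 3
    n_incomplete_blocks: int = 10
    field_sigma2_block: tuple[float, float] = (0.05, 0.05)  # control, Al
    field_sigma2_plot: tuple[float, float] = (0.20, 0.22)
    field_sigma_rep: float = 0.15
    include_checks: bool = True  # BR007 once + SC283 nine times per replicate
    # hydroponics design
    n_blocks: int = 2
    n_plants: int = 7
    hydro_sigma2_e_log: float = 0.056
    hydro_sigma_block_log: float = 0.10
    hydro_plant_sd_pct: float = 5.0
    hydro_growth_mean_cm: float = 8.0
    hydro_growth_sd_cm: float = 1.0
    hydro_initial_length_cm: float = 5.0
    hydro_check_rnrg_pct: tuple[float, float] = (117.0, 12.0)  # ATF10B, ATF8B
    # hybrid split-plot trial (2 treatments x 4 whole plots x 8 subplots)
    hybrid_grand_mean: float = 3.71
    hybrid_treatment_effect: float = 0.47  # +control / -Al
    hybrid_allele_effect: float = 0.50  # yield gain per tolerance allele
    hybrid_dominance: float = 0.0  # deviation of single-copy hybrids from additivity
    hybrid_n_wholeplots: int = 4
    # error variances back-solved from the reported LSDs (0.90 whole-plot
    # stratum, 0.45 subplot stratum): MS_wp = (0.90/0.6117)^2, MS_sub =
    # (0.45/0.5045)^2, sigma2_wp = (MS_wp - MS_sub)/8
    hybrid_sigma2_wholeplot: float = 0.171
    hybrid_sigma2_subplot: float = 0.796

    def __post_init__(self):
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        k = len(self.trait_names)
        for name in ("trait_means", "polygenic_sd", "blue_error_var"):
            if len(getattr(self, name)) != k:
                raise ValueError(f"{name} must have one entry per trait")
        sig = self.polygenic_covariance()
        if np.linalg.eigvalsh(sig).min() < -1e-10:
            raise ValueError("polygenic covariance is not positive semi-definite")
        for q in self.qtl:
            idx = int(q.chromosome) - 1
            if not 0 <= idx < len(self.chrom_lengths):
                raise ValueError(f"QTL chromosome {q.chromosome} outside the map")
            if q.position_cM > self.chrom_lengths[idx]:
                raise ValueError(
                    f"chromosome {q.chromosome} is shorter than QTL position "
                    f"{q.position_cM} cM"
                )

    def polygenic_covariance(self) -> np.ndarray:
        sd = np.asarray(self.polygenic_sd)
        corr = np.asarray(self.polygenic_corr, dtype=float)
        return corr * np.outer(sd, sd)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = [k for k in d if k not in known]
        if bad:
            raise ValueError(f"unknown config key(s): {bad}")
        d = dict(d)
        if "qtl" in d:
            d["qtl"] = tuple(
                QTLSpec(str(q[0]), float(q[1]), tuple(float(e) for e in q[2]))
                if not isinstance(q, QTLSpec) else q
                for q in d["qtl"]
            )
        for key in ("chrom_lengths", "trait_names", "trait_means", "polygenic_sd",
                    "blue_error_var", "field_sigma2_block", "field_sigma2_plot",
                    "hydro_check_rnrg_pct"):
            if key in d:
                d[key] = tuple(d[key])
        if "polygenic_corr" in d:
            d["polygenic_corr"] = tuple(tuple(row) for row in d["polygenic_corr"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qtl"] = [[q.chromosome, q.position_cM, list(q.effects)] for q in self.qtl]
        return d


# ---------------------------------------------------------------------------
# genome


def simulate_map(config: SimulationConfig) -> GeneticMap:
    """Deterministic evenly spaced map; QTL positions are snapped onto markers
    so they are exactly reachable by the scan grid."""
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    raw = config.n_markers * lengths / lengths.sum()
    counts = np.maximum(np.floor(raw).astype(int), 2)
    # largest-remainder top-up to the exact total
    while counts.sum() < config.n_markers:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > config.n_markers:
        i = np.argmin(raw - counts + np.where(counts <= 2, np.inf, 0))
        counts[i] -= 1
    rows = []
    for ci, (L, k) in enumerate(zip(lengths, counts), start=1):
        pos = np.round(np.linspace(0.0, L, k), 1)
        for q in config.qtl:
            if q.chromosome == str(ci):
                pos[np.argmin(np.abs(pos - q.position_cM))] = q.position_cM
        pos = np.unique(pos)
        rows.extend((f"c{ci}m{j + 1:03d}", str(ci), p) for j, p in enumerate(pos))
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "position_cM"]))


def simulate_ril_genotypes(gmap: GeneticMap, n_lines: int, seed) -> GenotypeMatrix:
    """RIL genotypes as independent two-state chains along each chromosome.

    Adjacent markers flip with probability R(d) (Haldane distance with the
    selfed-RIL expansion); marginal P(B) = 0.5 at every locus.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for chrom in gmap.chromosomes:
        pos = gmap.positions(chrom)
        names = gmap.chromosome_table(chrom)["marker"].tolist()
        g = np.empty((n_lines, len(pos)), dtype=float)
        g[:, 0] = rng.random(n_lines) < 0.5
        R = ril_recombination_fraction(np.diff(pos))
        flips = rng.random((n_lines, len(pos) - 1)) < R[None, :]
        for j in range(1, len(pos)):
            g[:, j] = np.abs(g[:, j - 1] - flips[:, j - 1])
        for name, col in zip(names, g.T):
            cols[name] = col
    line_ids = [f"RIL{i + 1:03d}" for i in range(n_lines)]
    return GenotypeMatrix(pd.DataFrame(cols, index=line_ids, columns=gmap.markers))


def qtl_regressors(geno: GenotypeMatrix, gmap: GeneticMap,
                   qtl: tuple[QTLSpec, ...]) -> np.ndarray:
    """0/1 genotype column (or conditional score) at each QTL position."""
    cols = []
    for q in qtl:
        t = gmap.chromosome_table(q.chromosome)
        hit = t.loc[np.isclose(t["position_cM"], q.position_cM), "marker"]
        if len(hit):
            cols.append(geno.data[hit.iloc[0]].to_numpy(dtype=float))
        else:
            grid = ScanGrid(
                table=pd.DataFrame(
                    {"chromosome": [q.chromosome], "position_cM": [q.position_cM]}
                ),
                step=1.0,
            )
            cols.append(genotype_probabilities(geno, gmap, grid).values[:, 0])
    return np.column_stack(cols) if cols else np.empty((geno.n_lines, 0))


def simulate_traits(
    geno: GenotypeMatrix,
    gmap: GeneticMap,
    config: SimulationConfig,
    seed,
    include_error: bool = False,
) -> pd.DataFrame:
    """True line values: mean + QTL effects + correlated polygenic background.

    With ``include_error`` an independent line-mean error (the stage-1 BLUE
    noise, variance ``blue_error_var``) is added per trait.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_lines
    X = qtl_regressors(geno, gmap, config.qtl)
    B = np.array([q.effects for q in config.qtl], dtype=float)  # n_qtl x n_traits
    poly = rng.multivariate_normal(
        np.zeros(len(config.trait_names)), config.polygenic_covariance(), size=n,
        method="cholesky",
    )
    Y = np.asarray(config.trait_means)[None, :] + (X @ B if len(B) else 0.0) + poly
    if include_error:
        Y = Y + rng.standard_normal(Y.shape) * np.sqrt(config.blue_error_var)
    return pd.DataFrame(Y, index=geno.line_ids, columns=list(config.trait_names))


def parent_true_values(config: SimulationConfig) -> pd.DataFrame:
    """Genetic values of the two parents (no polygenic deviation)."""
    B = np.array([q.effects for q in config.qtl], dtype=float)
    mu = np.asarray(config.trait_means)
    vals = np.vstack([mu, mu + B.sum(axis=0)])
    return pd.DataFrame(
        vals, index=[config.parent_a, config.parent_b], columns=list(config.trait_names)
    )


# ---------------------------------------------------------------------------
# phenotyping experiments


def simulate_field_trial(
    true_traits: pd.DataFrame, config: SimulationConfig, seed
) -> pd.DataFrame:
    """Plot-level yields for the paired control/Al incomplete-block trials.

    Each replicate contains every RIL once plus, if configured, the A parent
    once and the B parent (tolerant check) nine times, randomised into
    incomplete blocks; environment-specific block and plot error variances.
    """
    rng = np.random.default_rng(seed)
    parents = parent_true_values(config)
    entries = list(true_traits.index)
    if config.include_checks:
        entries = entries + [config.parent_a] + [config.parent_b] * 9
    truth = pd.concat([true_traits, parents])
    rows = []
    for ei, env in enumerate(("control", "Al")):
        g = truth["Gy_control" if env == "control" else "Gy_Al"]
        s2b = config.field_sigma2_block[ei]
        s2e = config.field_sigma2_plot[ei]
        for rep in range(1, config.n_replicates + 1):
            rep_eff = rng.normal(0.0, config.field_sigma_rep)
            order = rng.permutation(len(entries))
            blocks = np.array_split(order, config.n_incomplete_blocks)
            for bi, block in enumerate(blocks, start=1):
                b_eff = rng.normal(0.0, np.sqrt(s2b))
                for k in block:
                    line = entries[k]
                    y = g.loc[line] + rep_eff + b_eff + rng.normal(0.0, np.sqrt(s2e))
                    rows.append((line, env, f"rep{rep}", f"b{bi}", float(y)))
    return pd.DataFrame(
        rows, columns=["line", "environment", "replicate", "block", "yield_t_ha"]
    )


def simulate_hydroponics(
    true_traits: pd.DataFrame, config: SimulationConfig, seed
) -> pd.DataFrame:
    """Plant-level root-length records for the two-block hydroponic screen.

    Line-by-block target RNRG is the line's true value (log10 percent scale)
    plus a block effect and block-level noise; each of the seven plants gets
    a control growth rate and an Al growth rate consistent with the target,
    plus plant-level percent-scale noise.  Tolerant/sensitive check NILs are
    included as labelled entries.
    """
    rng = np.random.default_rng(seed)
    true_log = true_traits["RNRG_log10"].copy()
    for name, pct in zip(("ATF10B", "ATF8B"), config.hydro_check_rnrg_pct):
        true_log.loc[name] = np.log10(pct)
    block_eff = rng.normal(0.0, config.hydro_sigma_block_log, size=config.n_blocks)
    rows = []
    for line, tval in true_log.items():
        for b in range(config.n_blocks):
            target_log = (
                tval
                + block_eff[b]
                + rng.normal(0.0, np.sqrt(config.hydro_sigma2_e_log))
            )
            target_pct = 10.0 ** target_log
            for plant in range(1, config.n_plants + 1):
                crgr = max(
                    rng.normal(config.hydro_growth_mean_cm, config.hydro_growth_sd_cm),
                    2.0,
                )
                rnrg_plant = target_pct + rng.normal(0.0, config.hydro_plant_sd_pct)
                alrgr = crgr * rnrg_plant / 100.0
                il = config.hydro_initial_length_cm
                rows.append(
                    (line, f"block{b + 1}", plant, il, il + crgr, il,
                     max(il + alrgr, 0.0))
                )
    return pd.DataFrame(
        rows, columns=["line", "block", "plant", "il_c", "fl_c", "il_Al", "fl_Al"]
    )


def simulate_hybrid_trial(config: SimulationConfig, seed) -> pd.DataFrame:
    """Split-plot yields for the 2 female x 4 male isogenic-hybrid factorial.

    Al treatment sits at the whole-plot level (completely randomised, four
    whole plots per treatment); the eight hybrids are subplots.  Expected
    marginal means under the default calibration: females 3.46 / 3.96 and
    environments 4.18 / 3.24 ton/ha, i.e. 0.5 ton/ha per tolerance allele.
    """
    rng = np.random.default_rng(seed)
    mean_dosage = np.mean([h[3] for h in HYBRID_TABLE])
    frac_single = np.mean([h[3] == 1 for h in HYBRID_TABLE])
    base = (
        config.hybrid_grand_mean
        - config.hybrid_allele_effect * mean_dosage
        - config.hybrid_dominance * frac_single
    )
    rows = []
    for treatment, sign in (("control", 1.0), ("Al", -1.0)):
        for w in range(1, config.hybrid_n_wholeplots + 1):
            wp = f"{treatment}-wp{w}"
            wp_err = rng.normal(0.0, np.sqrt(config.hybrid_sigma2_wholeplot))
            for hybrid, female, male, dosage in HYBRID_TABLE:
                y = (
                    base
                    + sign * config.hybrid_treatment_effect
                    + wp_err
                    + config.hybrid_allele_effect * dosage
                    + config.hybrid_dominance * (dosage == 1)
                    + rng.normal(0.0, np.sqrt(config.hybrid_sigma2_subplot))
                )
                rows.append((wp, treatment, hybrid, female, male, dosage, float(y)))
    return pd.DataFrame(
        rows,
        columns=["whole_plot", "treatment", "hybrid", "female", "male", "dosage",
                 "yield_t_ha"],
    )


# ---------------------------------------------------------------------------
# one-call dataset


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    seed: int
    gmap: GeneticMap
    genotypes: GenotypeMatrix
    true_traits: pd.DataFrame
    field: pd.DataFrame
    hydro: pd.DataFrame
    hybrid: pd.DataFrame


def simulate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Generate every pipeline input from one global seed."""
    gmap = simulate_map(config)
    geno = simulate_ril_genotypes(gmap, config.n_lines, child_seed(seed, "genotypes"))
    truth = simulate_traits(geno, gmap, config, child_seed(seed, "traits"))
    return SyntheticDataset(
        config=config,
        seed=int(seed),
        gmap=gmap,
        genotypes=geno,
        true_traits=truth,
        field=simulate_field_trial(truth, config, child_seed(seed, "field")),
        hydro=simulate_hydroponics(truth, config, child_seed(seed, "hydro")),
        hybrid=simulate_hybrid_trial(config, child_seed(seed, "hybrid")),
    )
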