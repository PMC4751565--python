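"""Replicated simulation studies: operating characteristics of the scan.

These run the stage-2 engine repeatedly on freshly simulated populations to
measure genome-wide type-I error, detection power, position accuracy and
effect/%GV calibration under the emulated study conditions (90 RILs, 344
markers, three correlated traits).  Traits are simulated at the line-mean
level with the configured BLUE-scale error, i.e. the stage-1 output the
scan consumes; the full plot-level path is exercised separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genmap import build_scan_grid, genotype_probabilities
from .mtqtl import MultiTraitQTLScan, effective_number_of_tests, sim_scan
from .simulate import SimulationConfig, simulate_map, simulate_ril_genotypes, \
    simulate_traits


def _rep_seed(seed: int, study: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(study, rep))


def type1_error_study(n_reps: int = 200, seed: int = 0,
                      config: SimulationConfig | None = None,
                      alpha: float = 0.05, step: float = 2.0) -> dict:
    """Genome-wide false-positive rate of the SIM scan under no QTL.

    Each replicate simulates genotypes and purely polygenic traits, applies
    the Li-Ji threshold at level ``alpha`` and counts replicates whose
    maximal profile point exceeds it.
    """
    config = (config or SimulationConfig()).replace(qtl=())
    gmap = simulate_map(config)
    grid = build_scan_grid(gmap, step)
    hits = 0
    for rep in range(n_reps):
        ss = _rep_seed(seed, 1, rep)
        s_geno, s_trait = ss.spawn(2)
        geno = simulate_ril_genotypes(gmap, config.n_lines, s_geno)
        traits = simulate_traits(geno, gmap, config, s_trait, include_error=True)
        scores = genotype_probabilities(geno, gmap, grid)
        m_eff = effective_number_of_tests(geno, gmap)
        thr = -np.log10(1.0 - (1.0 - alpha) ** (1.0 / m_eff))
        scan = sim_scan(traits, scores)
        if np.nanmax(scan.table["neglog10p"].to_numpy()) > thr:
            hits += 1
    return {"rate": hits / n_reps, "n_reps": n_reps, "alpha": alpha}


def recovery_study(n_reps: int = 200, seed: int = 0,
                   config: SimulationConfig | None = None,
                   step: float = 2.0) -> pd.DataFrame:
    """Full-protocol recovery of the two configured QTL across replicates.

    Runs SIM -> CIM -> backward elimination per replicate and records, for
    each true QTL, whether a final QTL landed on its chromosome, the nearest
    estimated position, the per-trait effect estimates there, and %GV.
    Returns one row per (replicate, true QTL).
    """
    config = config or SimulationConfig()
    gmap = simulate_map(config)
    rows = []
    for rep in range(n_reps):
        ss = _rep_seed(seed, 2, rep)
        s_geno, s_trait = ss.spawn(2)
        geno = simulate_ril_genotypes(gmap, config.n_lines, s_geno)
        traits = simulate_traits(geno, gmap, config, s_trait, include_error=True)
        model = MultiTraitQTLScan(
            step=step, error_floors=list(config.blue_error_var),
            parent_a=config.parent_a, parent_b=config.parent_b,
        ).fit(geno, traits, genetic_map=gmap)
        qtl = model.qtl_
        for true_q in config.qtl:
            sub = qtl[qtl["chromosome"].astype(str) == true_q.chromosome]
            row = {"rep": rep, "chromosome": true_q.chromosome,
                   "true_position_cM": true_q.position_cM,
                   "detected": not sub.empty}
            if not sub.empty:
                nearest = (sub["position_cM"] - true_q.position_cM).abs().idxmin()
                hit = sub.loc[nearest]
                row["position_cM"] = float(hit["position_cM"])
                row["position_error_cM"] = abs(
                    float(hit["position_cM"]) - true_q.position_cM)
                at_pos = qtl[qtl["position_cM"] == hit["position_cM"]]
                for _, r in at_pos[at_pos["chromosome"].astype(str)
                                   == true_q.chromosome].iterrows():
                    row[f"effect_{r['trait']}"] = float(r["effect"])
                gv = model.percent_gv_
                label = hit["qtl"]
                if label in gv.index:
                    for trait in traits.columns:
                        row[f"pct_gv_{trait}"] = float(gv.loc[label, trait])
            rows.append(row)
    return pd.DataFrame(rows)


def hybrid_calibration_study(n_reps: int = 40, seed: int = 0,
                             config: SimulationConfig | None = None) -> dict:
    """Average split-plot marginal means and dosage coefficient over trials."""
    from .hybrid import DosageCovariateModel, SplitPlotAnova
    from .simulate import simulate_hybrid_trial

    config = config or SimulationConfig()
    rows = []
    for rep in range(n_reps):
        plots = simulate_hybrid_trial(config, _rep_seed(seed, 3, rep))
        m = SplitPlotAnova().fit(plots)
        d = DosageCovariateModel().fit(plots).result_
        rows.append({
            "female_ATF13A": m.means_["female"]["ATF13A"],
            "female_ATF14A": m.means_["female"]["ATF14A"],
            "env_control": m.means_["treatment"]["control"],
            "env_Al": m.means_["treatment"]["Al"],
            "lsd_female": m.lsd_["female"],
            "lsd_treatment": m.lsd_["treatment"],
            "dosage_coefficient": d.coefficient,
            "factor_substitution_effect": d.factor_substitution_effect,
        })
    out = pd.DataFrame(rows).mean().to_dict()
    out["n_reps"] = n_reps
    return out
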