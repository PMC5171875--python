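"""Synthetic two-sample summary statistics with known ground truth.

Simulation happens at the summary level: true instrument strengths and
direct (pleiotropic) effects are drawn, the true SNP-outcome association is
``beta_causal * gamma + alpha``, and observed betas get independent normal
sampling error on both sides — the exact generative model the estimators
assume, so parameter recovery is testable without individual-level data.

Also provides a deterministic liver-enzyme fixture (4 ALT / 14 ALP / 26 GGT
instruments with footnote rsIDs and a pleiotropy-tag table) used by the
demo pipeline and bookkeeping tests.
"""
from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .errors import ConfigurationError
from .types import GwasAssociation

REGIMES = ("none", "balanced", "directional_inside", "directional_inside_violated")

#: Non-palindromic allele pairs used for randomized orientations.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of one synthetic two-sample dataset."""

    beta_causal: float
    n_snps: int
    gamma_low: float = 0.1
    gamma_high: float = 0.5
    se_gamma: float = 0.01
    se_big_gamma: float = 0.02
    pleiotropy_regime: str = "none"
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.0
    invalid_fraction: float = 0.0
    inside_violation_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pleiotropy_regime not in REGIMES:
            raise ConfigurationError(
                f"unknown pleiotropy regime {self.pleiotropy_regime!r}; "
                f"expected one of {REGIMES}"
            )
        if not (0 <= self.invalid_fraction <= 1):
            raise ConfigurationError("invalid_fraction must be in [0, 1]")
        if self.se_gamma <= 0 or self.se_big_gamma <= 0:
            raise ConfigurationError("sampling SEs must be positive")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.pleiotropy_regime == "none" and self.invalid_fraction > 0:
            raise ConfigurationError("regime 'none' requires invalid_fraction = 0")
        if self.pleiotropy_regime == "balanced" and self.mu_alpha != 0:
            raise ConfigurationError("balanced pleiotropy requires mu_alpha = 0")
        if not (-1 <= self.inside_violation_corr <= 1):
            raise ConfigurationError("inside_violation_corr must be in [-1, 1]")


@dataclass
class SimulatedDataset:
    """Output of :func:`simulate_two_sample`: tables plus per-SNP truth."""

    exposure: list[GwasAssociation]
    outcome: list[GwasAssociation]
    truth: SimulationTruth
    true_gamma: np.ndarray
    alpha: np.ndarray
    outcome_flipped: np.ndarray

    def write(self, out_dir: str | Path, stem: str = "sim") -> dict[str, Path]:
        from .summary_io import write_summary_table

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "exposure": out_dir / f"{stem}_exposure.tsv",
            "outcome": out_dir / f"{stem}_outcome.tsv",
            "truth": out_dir / f"{stem}_truth.json",
        }
        write_summary_table(self.exposure, paths["exposure"])
        write_summary_table(self.outcome, paths["outcome"])
        paths["truth"].write_text(
            json.dumps(
                {
                    "truth": asdict(self.truth),
                    "true_gamma": self.true_gamma.tolist(),
                    "alpha": self.alpha.tolist(),
                    "outcome_flipped": self.outcome_flipped.tolist(),
                },
                indent=2,
            )
            + "\n"
        )
        return paths


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    # GwasAssociation requires p in (0, 1]; clamp underflow to the smallest float
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _draw_alpha(truth: SimulationTruth, gamma: np.ndarray, rng) -> np.ndarray:
    n = truth.n_snps
    alpha = np.zeros(n)
    n_invalid = int(round(truth.invalid_fraction * n))
    if truth.pleiotropy_regime == "none" or n_invalid == 0:
        return alpha
    invalid = rng.permutation(n)[:n_invalid]
    if truth.pleiotropy_regime in ("balanced", "directional_inside"):
        alpha[invalid] = rng.normal(truth.mu_alpha, truth.sigma_alpha, n_invalid)
    else:  # directional_inside_violated: direct effects track instrument strength
        rho = truth.inside_violation_corr
        g_sub = gamma[invalid]
        sd_g = np.std(g_sub) or 1.0
        z_g = (g_sub - np.mean(g_sub)) / sd_g
        eps = rng.standard_normal(n_invalid)
        alpha[invalid] = truth.mu_alpha + truth.sigma_alpha * (
            rho * z_g + np.sqrt(1 - rho * rho) * eps
        )
    return alpha


def simulate_two_sample(truth: SimulationTruth) -> SimulatedDataset:
    """Draw one synthetic exposure/outcome summary-table pair.

    True instrument strengths come from Uniform(gamma_low, gamma_high);
    direct effects follow the pleiotropy regime; the true SNP-outcome
    association is ``beta_causal * gamma + alpha``; observed betas add
    independent normal noise with the stated SEs. Allele orientations are
    randomized — roughly half the outcome rows report the opposite effect
    allele with a negated beta — so harmonization is exercised end to end.
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n_snps
    gamma = rng.uniform(truth.gamma_low, truth.gamma_high, n)
    alpha = _draw_alpha(truth, gamma, rng)
    big_gamma = truth.beta_causal * gamma + alpha

    se_g = np.full(n, float(truth.se_gamma))
    se_G = np.full(n, float(truth.se_big_gamma))
    gamma_hat = rng.normal(gamma, se_g)
    big_gamma_hat = rng.normal(big_gamma, se_G)
    p_exp = _two_sided_p(gamma_hat, se_g)
    p_out = _two_sided_p(big_gamma_hat, se_G)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), n)
    flipped = rng.random(n) < 0.5

    exposure, outcome = [], []
    for j in range(n):
        snp = f"rs{1000000 + j}"
        ea, oa = _ALLELE_PAIRS[pair_idx[j]]
        exposure.append(
            GwasAssociation(
                snp_id=snp,
                effect_allele=ea,
                other_allele=oa,
                beta=float(gamma_hat[j]),
                se=float(se_g[j]),
                p_value=float(p_exp[j]),
                trait_id="exposure",
            )
        )
        if flipped[j]:
            out_ea, out_oa, out_beta = oa, ea, -float(big_gamma_hat[j])
        else:
            out_ea, out_oa, out_beta = ea, oa, float(big_gamma_hat[j])
        outcome.append(
            GwasAssociation(
                snp_id=snp,
                effect_allele=out_ea,
                other_allele=out_oa,
                beta=out_beta,
                se=float(se_G[j]),
                p_value=float(p_out[j]),
                trait_id="outcome",
            )
        )
    return SimulatedDataset(
        exposure=exposure,
        outcome=outcome,
        truth=truth,
        true_gamma=gamma,
        alpha=alpha,
        outcome_flipped=flipped,
    )


# --------------------------------------------------------------------------
# Replicate harness (used by the simulate CLI subcommand and recovery tests)
# --------------------------------------------------------------------------


def run_replicates(
    truth: SimulationTruth,
    n_reps: int,
    seed: int,
    egger_residual_variance: str = "none",
) -> dict:
    """Run ``n_reps`` independent datasets and summarize estimator behavior.

    Each replicate reuses ``truth`` with a derived seed, harmonizes the
    randomized-orientation tables, and records the IVW, MR-Egger (when
    >= 3 SNPs) and weighted-median point estimates plus IVW CI coverage of
    the true causal effect and the Egger-intercept p-value.
    """
    from .estimators import ivw_fixed, mr_egger, weighted_median_point
    from .summary_io import harmonize

    seed_seq = np.random.SeedSequence(entropy=seed)
    child_seeds = seed_seq.generate_state(n_reps)
    ivw_betas, egger_betas, wm_betas = [], [], []
    covered, intercept_ps = [], []
    from dataclasses import replace as _replace

    for rep_seed in child_seeds:
        rep_truth = _replace(truth, seed=int(rep_seed))
        data = simulate_two_sample(rep_truth)
        insts = harmonize(data.exposure, data.outcome)
        ivw = ivw_fixed(insts)
        ivw_betas.append(ivw.beta)
        covered.append(ivw.ci_low <= truth.beta_causal <= ivw.ci_high)
        if len(insts) >= 3:
            egger = mr_egger(insts, residual_variance=egger_residual_variance)
            egger_betas.append(egger.beta)
            intercept_ps.append(egger.egger_intercept_p)
            wm_betas.append(weighted_median_point(insts))

    ivw_arr = np.asarray(ivw_betas)
    summary = {
        "n_reps": n_reps,
        "beta_causal": truth.beta_causal,
        "ivw_mean": float(np.mean(ivw_arr)),
        "ivw_sd": float(np.std(ivw_arr, ddof=1)),
        "ivw_bias": float(np.mean(ivw_arr) - truth.beta_causal),
        "ivw_coverage": float(np.mean(covered)),
    }
    if egger_betas:
        egger_arr = np.asarray(egger_betas)
        wm_arr = np.asarray(wm_betas)
        p_arr = np.asarray(intercept_ps)
        summary.update(
            {
                "egger_mean": float(np.mean(egger_arr)),
                "egger_bias": float(np.mean(egger_arr) - truth.beta_causal),
                "wm_mean": float(np.mean(wm_arr)),
                "wm_bias": float(np.mean(wm_arr) - truth.beta_causal),
                "egger_intercept_rejection_rate": float(np.mean(p_arr < 0.05)),
            }
        )
    return summary


# --------------------------------------------------------------------------
# Liver-enzyme demo fixture
# --------------------------------------------------------------------------

_ALT_SNPS = [
    ("rs738409", "PNPLA3"),
    ("rs2954021", "TRIB1"),
    ("rs6834314", "MAPK10, HSD17B13"),
    ("rs10883437", "CPN1"),
]

_ALP_NAMED = [
    ("rs174601", "C11orf10, FADS1, FADS2"),
    ("rs314253", "ASGR1, DLG4"),
    ("rs2954021", "TRIB1"),
    ("rs579459", "ABO"),
    ("rs6984305", "PPP1R3B"),
]

_GGT_NAMED = [
    ("rs516246", "FUT2"),
    ("rs7310409", "HNF1A"),
    ("rs1260326", "C2orf16, GCKR"),
]

#: (snp_id, outcome_id) pairs mirroring the exclusion footnotes of the
#: reference analysis; CAD tags are emitted for both outcome panels.
_TAG_TABLE = [
    ("rs2954021", "cad_hapmap"),
    ("rs2954021", "cad_1000g"),
    ("rs174601", "cad_hapmap"),
    ("rs174601", "cad_1000g"),
    ("rs314253", "cad_hapmap"),
    ("rs314253", "cad_1000g"),
    ("rs579459", "cad_hapmap"),
    ("rs579459", "cad_1000g"),
    ("rs6984305", "cad_hapmap"),
    ("rs6984305", "cad_1000g"),
    ("rs516246", "cad_hapmap"),
    ("rs516246", "cad_1000g"),
    ("rs7310409", "cad_hapmap"),
    ("rs7310409", "cad_1000g"),
    ("rs1260326", "cad_hapmap"),
    ("rs1260326", "cad_1000g"),
    ("rs2954021", "t2dm"),
    ("rs516246", "t2dm"),
    ("rs1260326", "t2dm"),
]

_GENE_LABELS = dict(_ALT_SNPS + _ALP_NAMED + _GGT_NAMED)

#: True causal effects (log-odds per unit exposure) used by the fixture.
_FIXTURE_EFFECTS = {
    ("alt", "cad_hapmap"): -0.2,
    ("alt", "cad_1000g"): -0.25,
    ("alt", "t2dm"): 1.0,
    ("alp", "cad_hapmap"): -0.2,
    ("alp", "cad_1000g"): -0.3,
    ("alp", "t2dm"): -0.1,
    ("ggt", "cad_hapmap"): 0.1,
    ("ggt", "cad_1000g"): 0.05,
    ("ggt", "t2dm"): -0.15,
}

FIXTURE_OUTCOMES = ("cad_hapmap", "cad_1000g", "t2dm")
FIXTURE_ENZYMES = ("alt", "alp", "ggt")


@dataclass
class FixtureBundle:
    """In-memory liver-enzyme fixture: exposure/outcome tables plus tags."""

    exposures: dict[str, list[GwasAssociation]]
    outcomes: dict[str, list[GwasAssociation]]
    tag_rows: list[tuple[str, str, str]] = field(default_factory=list)
    effects: dict[tuple[str, str], float] = field(default_factory=dict)


def _fixture_snp_lists() -> dict[str, list[tuple[str, str]]]:
    alp = list(_ALP_NAMED) + [(f"rs82{i:05d}", "") for i in range(9)]
    ggt = list(_GGT_NAMED) + [(f"rs91{i:05d}", "") for i in range(23)]
    return {"alt": list(_ALT_SNPS), "alp": alp, "ggt": ggt}


def make_liver_enzyme_fixture(seed: int = 38813) -> FixtureBundle:
    """Build the deterministic demo fixture: 4 ALT, 14 ALP and 26 GGT
    instruments (footnote rsIDs, synthetic betas/SEs), outcome tables for
    two CAD/MI panels and T2DM, and the pleiotropy-tag rows.

    The shared SNP rs2954021 appears in both the ALT and ALP sets. The
    first ALT instrument deliberately dominates the IVW weight so the
    weight-share rule routes ALT to MR-Egger, as in the reference analysis.
    """
    rng = np.random.default_rng(seed)
    snp_lists = _fixture_snp_lists()

    exposures: dict[str, list[GwasAssociation]] = {}
    gamma_by_snp: dict[tuple[str, str], float] = {}
    # rs2954021 sits in both the ALT and ALP sets: alleles must agree per SNP
    alleles_by_snp: dict[str, tuple[str, str]] = {}
    for enzyme, snps in snp_lists.items():
        records = []
        for k, (snp_id, _gene) in enumerate(snps):
            if enzyme == "alt" and k == 0:
                gamma = 0.60  # dominant instrument: > 50% of IVW weight
            else:
                gamma = float(rng.uniform(0.08, 0.20))
            se = gamma / float(rng.uniform(8.0, 15.0))
            if snp_id not in alleles_by_snp:
                alleles_by_snp[snp_id] = _ALLELE_PAIRS[
                    int(rng.integers(0, len(_ALLELE_PAIRS)))
                ]
            ea, oa = alleles_by_snp[snp_id]
            records.append(
                GwasAssociation(
                    snp_id=snp_id,
                    effect_allele=ea,
                    other_allele=oa,
                    beta=gamma,
                    se=se,
                    p_value=float(_two_sided_p(np.array([gamma]), np.array([se]))[0]),
                    trait_id=enzyme,
                )
            )
            gamma_by_snp[(enzyme, snp_id)] = gamma
        exposures[enzyme] = records

    # direct effects for tagged SNPs so pleiotropy exclusion visibly matters
    direct = {snp: float(rng.normal(0.08, 0.02)) for snp, _ in _TAG_TABLE}

    outcomes: dict[str, list[GwasAssociation]] = {}
    for outcome_id in FIXTURE_OUTCOMES:
        seen: set[str] = set()
        records = []
        for enzyme in FIXTURE_ENZYMES:
            effect = _FIXTURE_EFFECTS[(enzyme, outcome_id)]
            for exp_rec in exposures[enzyme]:
                if exp_rec.snp_id in seen:
                    continue
                seen.add(exp_rec.snp_id)
                tagged = any(
                    s == exp_rec.snp_id and o == outcome_id for s, o in _TAG_TABLE
                )
                truth_beta = effect * exp_rec.beta + (direct[exp_rec.snp_id] if tagged else 0.0)
                se = float(rng.uniform(0.015, 0.04))
                beta = float(rng.normal(truth_beta, se))
                if rng.random() < 0.5:  # randomized reporting orientation
                    ea, oa, beta = exp_rec.other_allele, exp_rec.effect_allele, -beta
                else:
                    ea, oa = exp_rec.effect_allele, exp_rec.other_allele
                records.append(
                    GwasAssociation(
                        snp_id=exp_rec.snp_id,
                        effect_allele=ea,
                        other_allele=oa,
                        beta=beta,
                        se=se,
                        p_value=float(_two_sided_p(np.array([beta]), np.array([se]))[0]),
                        trait_id=outcome_id,
                    )
                )
        outcomes[outcome_id] = records

    tag_rows = [
        (snp, outcome, _GENE_LABELS.get(snp, "")) for snp, outcome in _TAG_TABLE
    ]
    return FixtureBundle(
        exposures=exposures,
        outcomes=outcomes,
        tag_rows=tag_rows,
        effects=dict(_FIXTURE_EFFECTS),
    )


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture as TSV/CSV/YAML files ready for ``mr run``."""
    from .summary_io import write_summary_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for enzyme, records in bundle.exposures.items():
        path = out_dir / f"exposure_{enzyme}.tsv"
        write_summary_table(records, path)
        paths[f"exposure_{enzyme}"] = path
    for outcome_id, records in bundle.outcomes.items():
        path = out_dir / f"outcome_{outcome_id}.tsv"
        write_summary_table(records, path)
        paths[f"outcome_{outcome_id}"] = path

    tag_path = out_dir / "pleiotropy_tags.csv"
    with tag_path.open("w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(["snp_id", "outcome_id", "gene_label", "source"])
        for snp, outcome, gene in bundle.tag_rows:
            writer.writerow([snp, outcome, gene, "fixture"])
    paths["tags"] = tag_path

    config = {
        "exposures": [
            {"id": enzyme, "path": f"exposure_{enzyme}.tsv"}
            for enzyme in bundle.exposures
        ],
        "outcomes": [
            {"id": outcome_id, "path": f"outcome_{outcome_id}.tsv", "binary": True}
            for outcome_id in bundle.outcomes
        ],
        "tags_path": "pleiotropy_tags.csv",
        "p_threshold": 5e-8,
        "r2_threshold": 0.8,
        "n_boot": 1000,
        "seed": 0,
        "egger_residual_variance": "none",
        "out_dir": "results",
    }
    import yaml

    config_path = out_dir / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=False))
    paths["config"] = config_path

    truth_path = out_dir / "fixture_truth.json"
    truth_path.write_text(
        json.dumps(
            {f"{e}->{o}": b for (e, o), b in bundle.effects.items()}, indent=2
        )
        + "\n"
    )
    paths["truth"] = truth_path
    return paths
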