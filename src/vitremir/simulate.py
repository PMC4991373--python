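"""Synthetic qPCR cohorts, amplification curves and SNP panels.

The generator emulates a two-group case/control study of miRNAs measured by
TaqMan-style qPCR: each reaction yields a threshold cycle (Ct) that is
inversely proportional to log template abundance,

    Ct = base_ct - log_E(abundance) + eps,    eps ~ N(0, ct_noise_sd),

with ``E`` the per-cycle amplification base in (1, 2].  Case samples carry a
multiplicative fold effect on abundance, so the configured effects are
recoverable downstream by efficiency-aware ddCt inversion.  Ct values past the
40-cycle detection threshold are recorded as undetected (NaN), mirroring the
truncation semantics of the instrument rather than a separate dropout process.

A small clinical roster of a real vitreous-biopsy cohort (13 controls with
non-vascular pathology, 13 neovascular AMD patients) ships with the package
and seeds the default group sizes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

DETECTION_LIMIT = 40.0

#: miRNAs carried through the validated panel: three disease-associated
#: targets, the plasma reference miR-16, and two array-stage candidates.
DEFAULT_PANEL = ("miR-146a", "miR-106b", "miR-152", "miR-16", "miR-205", "miR-548a")

#: Case-vs-control multiplicative effects observed in vitreous humour
#: (increase ~3.02 for miR-146a; decreases to 0.23 and 0.33 for miR-106b and
#: miR-152); reference and non-validated miRNAs are simulated as null.
DEFAULT_FOLD_EFFECTS = {
    "miR-146a": 3.02,
    "miR-106b": 0.23,
    "miR-152": 0.33,
    "miR-16": 1.0,
    "miR-205": 1.0,
    "miR-548a": 1.0,
}

DEFAULT_BASE_CT = {
    "miR-146a": 26.0,
    "miR-106b": 30.0,
    "miR-152": 28.0,
    "miR-16": 20.0,
    "miR-205": 30.0,
    "miR-548a": 32.0,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic two-group qPCR cohort.

    ``ct_noise_sd`` is the total per-reaction Gaussian noise on the cycle
    scale (technical + biological); ``efficiency_base`` may be a scalar
    applied to every miRNA or a per-miRNA map, each value in (1, 2].
    """

    n_control: int = 13
    n_case: int = 13
    mir_panel: Sequence[str] = DEFAULT_PANEL
    fold_effects: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FOLD_EFFECTS))
    base_ct: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_CT))
    ct_noise_sd: float = 1.0
    efficiency_base: Mapping[str, float] | float = 1.75
    efficiency_jitter_sd: float = 0.0
    hemolysis_rate: float = 0.15
    matrix: str = "vitreous"
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_control < 2:
            raise ConfigError("n_control must be >= 2")
        if self.n_case < 2:
            raise ConfigError("n_case must be >= 2")
        if not self.mir_panel:
            raise ConfigError("mir_panel must be non-empty")
        if self.ct_noise_sd < 0:
            raise ConfigError("ct_noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not 0.0 <= self.hemolysis_rate < 1.0:
            raise ConfigError("hemolysis_rate must be in [0, 1)")
        if self.matrix not in ("vitreous", "plasma"):
            raise ConfigError("matrix must be 'vitreous' or 'plasma'")
        for mir in self.mir_panel:
            fe = self.fold_effects.get(mir, 1.0)
            if not fe > 0:
                raise ConfigError(f"fold_effects[{mir}] must be > 0")
            e = self.base_for(mir)
            if not 1.0 < e <= 2.0:
                raise ConfigError(f"efficiency_base[{mir}] must be in (1, 2]")
            if mir not in self.base_ct:
                raise ConfigError(f"base_ct missing entry for {mir}")

    def base_for(self, mir: str) -> float:
        if isinstance(self.efficiency_base, Mapping):
            return float(self.efficiency_base[mir])
        return float(self.efficiency_base)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class SimTruth:
    """Ground truth behind a simulated cohort, for parameter-recovery tests."""

    abundance: pd.DataFrame          # samples x miRNAs, true relative abundance (> 0)
    efficiency: pd.Series            # per reaction_id, true amplification base
    groups: pd.Series                # per sample_id, 'control' | 'case'
    ct_true: pd.DataFrame            # samples x miRNAs, noise-free Ct (pre-truncation)


def _hemolysis_indices(rng: np.random.Generator, n: int, rate: float, sigma: float = 0.5) -> np.ndarray:
    """Lognormal hemolysis index with P(index > 1) ~= rate, independent of group."""
    if rate <= 0.0:
        mu = -6.0 * sigma
    else:
        mu = sigma * stats.norm.ppf(rate)
    return np.exp(rng.normal(mu, sigma, size=n))


def simulate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate reaction records, sample metadata and ground truth.

    Returns
    -------
    records : DataFrame with columns reaction_id, sample_id, mir_id,
        replicate, ct (NaN when past the 40-cycle detection threshold),
        efficiency (true per-reaction base).
    meta : DataFrame with columns sample_id, group, matrix, age, sex,
        hemolysis_index (NaN for vitreous), clinical_flags.
    truth : SimTruth
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples = [f"C{i+1}" for i in range(config.n_control)] + [
        f"AMD{i+1}" for i in range(config.n_case)
    ]
    groups = pd.Series(
        ["control"] * config.n_control + ["case"] * config.n_case,
        index=pd.Index(samples, name="sample_id"),
        name="group",
    )

    mirs = list(config.mir_panel)
    abundance = pd.DataFrame(1.0, index=groups.index, columns=mirs)
    for mir in mirs:
        fe = float(config.fold_effects.get(mir, 1.0))
        abundance.loc[groups == "case", mir] = fe

    ct_true = pd.DataFrame(index=groups.index, columns=mirs, dtype=float)
    for mir in mirs:
        e = config.base_for(mir)
        ct_true[mir] = config.base_ct[mir] - np.log(abundance[mir].to_numpy()) / np.log(e)

    rows = []
    eff_by_reaction = {}
    for sample in samples:
        for mir in mirs:
            for rep in range(1, config.n_replicates + 1):
                rid = f"{sample}:{mir}:{rep}"
                e = config.base_for(mir)
                if config.efficiency_jitter_sd > 0:
                    e = float(np.clip(rng.normal(e, config.efficiency_jitter_sd), 1.05, 2.0))
                eff_by_reaction[rid] = e
                ct = ct_true.at[sample, mir]
                if config.ct_noise_sd > 0:
                    ct = ct + rng.normal(0.0, config.ct_noise_sd)
                rows.append(
                    {
                        "reaction_id": rid,
                        "sample_id": sample,
                        "mir_id": mir,
                        "replicate": rep,
                        "ct": np.nan if ct > DETECTION_LIMIT else float(ct),
                        "efficiency": e,
                    }
                )
    records = pd.DataFrame(rows)

    ages = np.where(
        groups.to_numpy() == "case",
        rng.normal(82.0, 9.0, size=len(samples)),
        rng.normal(67.0, 11.0, size=len(samples)),
    ).round()
    sexes = rng.choice(["F", "M"], size=len(samples), p=[0.77, 0.23])
    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups.to_numpy(),
            "matrix": config.matrix,
            "age": ages,
            "sex": sexes,
            "hemolysis_index": (
                _hemolysis_indices(rng, len(samples), config.hemolysis_rate)
                if config.matrix == "plasma"
                else np.nan
            ),
            "clinical_flags": "",
        }
    )

    truth = SimTruth(
        abundance=abundance,
        efficiency=pd.Series(eff_by_reaction, name="efficiency"),
        groups=groups,
        ct_true=ct_true,
    )
    return records, meta, truth


def simulate_curves(
    records: pd.DataFrame,
    truth: SimTruth,
    cycles: int = 40,
    seed: int = 0,
    *,
    threshold: float = 1.0,
    fmax: float = 10.0,
    baseline: float = 0.05,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Per-cycle fluorescence traces for each reaction record.

    Fluorescence follows the saturating-exponential model

        F(c) = Fmax * F0 * E^c / (Fmax + F0 * E^c) + baseline + noise,

    with F0 set so the pure-exponential phase crosses ``threshold`` at the
    recorded Ct (F0 = threshold * E^-Ct); undetected reactions get an F0
    placing the crossing well past the last cycle.  ``fmax=np.inf`` with
    ``baseline=0`` gives the pure exponential limit F(c)/F(c-1) = E.
    Long-format output: reaction_id, sample_id, mir_id, cycle, fluorescence.
    """
    if cycles < 25:
        raise ConfigError("cycles must be >= 25")
    rng = np.random.default_rng(seed)
    c = np.arange(1, cycles + 1, dtype=float)

    frames = []
    for row in records.itertuples(index=False):
        e = truth.efficiency.get(row.reaction_id, row.efficiency)
        ct = row.ct if np.isfinite(row.ct) else cycles + 5.0
        f0 = threshold * e ** (-ct)
        expo = f0 * e**c
        if np.isinf(fmax):
            f = expo
        else:
            f = fmax * expo / (fmax + expo)
        f = f + baseline
        if noise_sd > 0:
            f = np.clip(f + rng.normal(0.0, noise_sd, size=cycles), 0.0, None)
        frames.append(
            pd.DataFrame(
                {
                    "reaction_id": row.reaction_id,
                    "sample_id": row.sample_id,
                    "mir_id": row.mir_id,
                    "cycle": c.astype(int),
                    "fluorescence": f,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_snp_panel(
    n_snps: int,
    motifs: pd.DataFrame,
    n_true: int,
    seed: int = 0,
    *,
    alt_p_range: tuple[float, float] = (1e-6, 1e-3),
) -> pd.DataFrame:
    """Association summary statistics with ``n_true`` planted motif hits.

    The planted SNPs are placed uniformly inside randomly chosen motif
    intervals with p-values uniform on ``alt_p_range``; the remaining SNPs
    are scattered over the motif-bearing chromosomes with p uniform on (0,1].
    Columns: rsid, chrom, pos, p_value, gene.
    """
    if n_true > n_snps:
        raise ConfigError("n_true must be <= n_snps")
    if motifs is None or len(motifs) == 0:
        raise ConfigError("motifs must be non-empty")
    rng = np.random.default_rng(seed)

    chroms = motifs["chrom"].unique()
    span_hi = int(motifs["end"].max() * 2)

    rows = []
    for i in range(n_true):
        m = motifs.iloc[int(rng.integers(0, len(motifs)))]
        pos = int(rng.integers(int(m["start"]), int(m["end"]) + 1))
        rows.append(
            {
                "rsid": f"rs_true{i+1}",
                "chrom": m["chrom"],
                "pos": pos,
                "p_value": float(rng.uniform(*alt_p_range)),
                "gene": m.get("gene", ""),
            }
        )
    for i in range(n_snps - n_true):
        rows.append(
            {
                "rsid": f"rs{i+1}",
                "chrom": str(rng.choice(chroms)),
                "pos": int(rng.integers(1, span_hi + 1)),
                "p_value": float(1.0 - rng.random()),  # uniform on (0, 1]
                "gene": "",
            }
        )
    return pd.DataFrame(rows)


def load_vitreous_roster() -> pd.DataFrame:
    """Clinical roster of the vitreous-biopsy cohort shipped with the package."""
    ref = importlib.resources.files("vitremir.data").joinpath("vitreous_cohort.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", na_values=["NA"])


def roster_summary(roster: pd.DataFrame) -> pd.DataFrame:
    """Baseline statistics per group: n, mean/SD age (population SD), % female.

    Group SDs use the population (n) denominator, matching how clinical
    baseline tables are usually tabulated.
    """
    out = []
    for group, sub in roster.groupby("group"):
        ages = sub["age"].to_numpy(dtype=float)
        out.append(
            {
                "group": group,
                "n": len(sub),
                "mean_age": float(np.mean(ages)),
                "sd_age": float(np.std(ages)),  # population SD
                "pct_female": 100.0 * float((sub["sex"] == "F").mean()),
            }
        )
    return pd.DataFrame(out).set_index("group")
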