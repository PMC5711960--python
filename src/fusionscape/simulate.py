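"""Synthetic fusion-cohort generator.

Builds a fully synthetic desk-scale study — toy genome annotation, reference
sequence, two callers' report files, sample metadata, an expression matrix
and a ground-truth table — with the statistical structure the analysis
pipeline assumes:

* right-skewed per-sample fusion burden (zero-inflated negative binomial);
* an Ig-fusion patient subgroup carrying a higher overall burden;
* recurrent hotspot partner genes (heavy-tailed catalog intensities,
  including an IGH-NSD2-like pair and a dominant IGK partner);
* same-chromosome read-through-like events concentrated on a dense
  chromosome-19 analog;
* caller-specific false positives with breakpoint jitter, same-gene-family
  decoys, low-support events and breakpoint-flank homology decoys;
* over-expression of fused genes in the expression matrix;
* subgroup structure (FISH-translocated patients IGH-heavy, high-hyperdiploid
  patients Ig-poor) and an age-burden correlation.

The ``myeloma_preset`` configuration is calibrated at construction time, by
solving expectation equations (zero-inflated NB moments and Poissonized
hotspot-occupancy formulas), so that the generated cohorts match the target
cohort statistics: burden mean 5.5 with 11.8% fusion-free patients, 47.3% of
patients with an Ig fusion, burden contrast 8.3 vs 3.8 between patients with
and without Ig fusions (conditional on at least one fusion), Ig fusions 36%
of unique pairs, recurrent fusions 28.8% and recurrent non-Ig 17.2%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq, least_squares

from .io import (
    MAPSPLICE_DIALECT,
    TOPHAT_DIALECT,
    collapse_calls,
    write_fusion_table,
    write_gene_annotation,
    write_gene_families,
    write_sample_metadata,
)
from .model import (
    Caller,
    DataError,
    FusionCall,
    GeneAnnotation,
    GeneFamilyTable,
    GeneRecord,
    SampleMeta,
    ig_class_for_symbol,
)

__all__ = ["SimConfig", "SimTruth", "SimulatedCohort", "simulate_cohort", "myeloma_preset"]

# ---------------------------------------------------------------------------
# toy genome layout
# ---------------------------------------------------------------------------

# (name, length in bp, number of gene slots); chr19 is the high-density
# analog, chr2/chr14/chr22 host the IGK/IGH/IGL loci
_CHROM_TABLE = [
    ("chr1", 900_000, 70),
    ("chr2", 860_000, 60),
    ("chr3", 820_000, 58),
    ("chr4", 780_000, 52),
    ("chr5", 750_000, 48),
    ("chr6", 720_000, 50),
    ("chr7", 690_000, 44),
    ("chr8", 660_000, 40),
    ("chr9", 630_000, 38),
    ("chr10", 600_000, 36),
    ("chr11", 580_000, 38),
    ("chr12", 560_000, 34),
    ("chr13", 540_000, 28),
    ("chr14", 520_000, 30),
    ("chr15", 500_000, 28),
    ("chr16", 480_000, 26),
    ("chr17", 460_000, 24),
    ("chr18", 440_000, 20),
    ("chr19", 500_000, 95),
    ("chr20", 400_000, 18),
    ("chr21", 360_000, 14),
    ("chr22", 420_000, 22),
]

_IGH_GENES = ["IGHM", "IGHD", "IGHG3", "IGHG1", "IGHA1", "IGHG2", "IGHG4", "IGHE", "IGHA2"]
_IGK_GENES = ["IGKC", "IGKJ1", "IGKV1-5", "IGKV2-24", "IGKV3-20", "IGKV4-1"]
_IGL_GENES = ["IGLJ1", "IGLC1", "IGLC2", "IGLC3", "IGLV1-40", "IGLV2-14"]

# named genes placed on their (real-genome) chromosomes; used as hotspot
# partners so the synthetic landscape reads like the myeloma one
_NAMED_GENES = {
    "chr1": ["JUN"],
    "chr2": ["BCL2L11"],
    "chr4": ["NSD2", "FGFR3", "CCNG2"],
    "chr6": ["TXNDC5"],
    "chr7": ["MAFK", "ACTB"],
    "chr11": ["CCND1", "IGHMBP2"],
    "chr12": ["UBC"],
    "chr15": ["B2M"],
    "chr16": ["WWOX"],
    "chr19": ["TPM4", "ISYNA1", "OAZ1", "CSNK1G2", "JUND", "FOSB"],
}

_FAMILY_GENES = {
    "HISTONE_H2B": ["HIST1H2BB", "HIST1H2BC", "HIST1H2BD", "HIST1H2BE", "HIST1H2BF", "HIST1H2BG"],
    "KRTAP": ["KRTAP1", "KRTAP2", "KRTAP3", "KRTAP4"],
}
_FAMILY_CHROM = {"HISTONE_H2B": "chr6", "KRTAP": "chr17"}

_ALIASES = {"WHSC1": "NSD2", "MMSET": "NSD2"}

# per-(cytogenetic group, light-chain phenotype) Ig class probabilities
# (IGH, IGK, IGL); translocated patients are IGH-heavy, kappa-phenotype
# patients essentially never express lambda fusions and vice versa
_CLASS_PROBS = {
    ("translocated", "kappa"): (0.52, 0.47, 0.01),
    ("translocated", "lambda"): (0.75, 0.02, 0.23),
    ("other", "kappa"): (0.10, 0.89, 0.01),
    ("other", "lambda"): (0.45, 0.03, 0.52),
}

TRUE = "true"
HOMOLOGY_DECOY = "homology_decoy"
FAMILY_DECOY = "family_decoy"
LOW_SUPPORT = "low_support"
FP_A = "callerA_only_fp"
FP_B = "callerB_only_fp"


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Generator configuration; fractions are probabilities in [0, 1].

    The ``calibrated_*`` fields are derived by :func:`myeloma_preset` (or
    :meth:`calibrate`) from the target cohort statistics; they may also be
    set directly for custom scenarios.
    """

    seed: int = 0
    n_patients: int = 255
    n_cell_lines: int = 71

    # per-patient burden: zero-inflated negative binomial
    burden_mean: float = 5.5
    burden_zero_fraction: float = 0.118
    burden_dispersion: float = 2.0

    # cell lines: zero-truncated negative binomial, lighter tail
    cell_line_burden_mean: float = 6.1
    cell_line_dispersion: float = 8.0

    # patient subgroup structure
    frac_kappa: float = 0.68
    frac_translocated: float = 0.35
    frac_hhmm: float = 0.20
    mult_translocated: float = 1.3
    mult_hhmm: float = 0.4

    # calibration targets (printed cohort statistics)
    target_pct_samples_ig: float = 0.473
    target_mean_with_ig: float = 8.3
    target_ig_share_unique: float = 0.36
    target_recurrent_share: float = 0.288
    target_recurrent_nonig_share: float = 0.172

    # hotspot catalogs
    n_hot_igh: int = 26
    n_hot_igk: int = 50
    n_hot_igl: int = 6
    n_hot_nonig: int = 100
    first_weight_igh: float = 0.28
    first_weight_igk: float = 0.45
    zipf_exponent: float = 0.8

    # event geometry and noise
    same_chr_fraction: float = 0.55
    breakpoint_jitter_sd: float = 15.0
    support_mean: float = 15.0
    duplicate_row_rate: float = 0.05
    fp_rate_a: float = 4.0
    fp_rate_b: float = 2.5
    family_decoy_rate: float = 0.5
    low_support_rate: float = 0.4
    homology_decoy_frac: float = 0.08

    # cell-line event model
    cell_line_ig_type_prob: float = 0.68
    cell_line_theta: float = 0.55
    cell_line_p_hot_ig: float = 0.45
    cell_line_p_hot_nonig: float = 0.25

    # expression
    expression_effect: float = 2.0
    expression_noise_sd: float = 1.0
    n_background_genes: int = 150

    # age
    age_mean: float = 56.6
    age_sd: float = 6.0
    age_burden_rho: float = 0.35

    # calibrated (derived) parameters
    calibrated: bool = False
    zi_pi: float = 0.0
    nb_mu: float = 5.5
    ig_intercept: float = 0.25
    ig_slope: float = 0.05
    theta_ig: float = 0.5
    p_hot_ig: float = 0.7
    p_hot_nonig: float = 0.7
    calibration_info: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for name in (
            "burden_zero_fraction",
            "frac_kappa",
            "frac_translocated",
            "frac_hhmm",
            "same_chr_fraction",
            "homology_decoy_frac",
            "duplicate_row_rate",
            "cell_line_ig_type_prob",
            "cell_line_theta",
            "cell_line_p_hot_ig",
            "cell_line_p_hot_nonig",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 1 or self.n_cell_lines < 0:
            raise DataError("need at least one patient")
        if self.frac_translocated + self.frac_hhmm > 1.0:
            raise DataError("subgroup fractions exceed 1")
        if self.burden_mean <= 0 or self.cell_line_burden_mean <= 0:
            raise DataError("burden means must be positive")

    # -- calibration -------------------------------------------------------

    def burden_pmf(self, n_max: int = 200) -> np.ndarray:
        """Zero-inflated NB pmf on 0..n_max using the calibrated zi/mu."""
        r = self.burden_dispersion
        p = r / (r + self.nb_mu)
        pmf = (1 - self.zi_pi) * sps.nbinom.pmf(np.arange(n_max + 1), r, p)
        pmf[0] += self.zi_pi
        return pmf

    def calibrate(self) -> "SimConfig":
        """Solve the derived parameters from the target statistics (in place).

        Raises :class:`DataError` if the targets are infeasible under the
        configured catalog/subgroup structure.
        """
        _calibrate_burden(self)
        _calibrate_ig_structure(self)
        self.calibrated = True
        return self


def _calibrate_burden(cfg: SimConfig) -> None:
    r = cfg.burden_dispersion
    m, z = cfg.burden_mean, cfg.burden_zero_fraction

    def f(pi: float) -> float:
        mu = m / (1 - pi)
        return pi + (1 - pi) * (r / (r + mu)) ** r - z

    nb0 = (r / (r + m)) ** r
    if nb0 > z:
        raise DataError(
            "infeasible burden model: plain NB zero mass already exceeds the "
            "target zero fraction; increase dispersion"
        )
    cfg.zi_pi = float(brentq(f, 0.0, z))
    cfg.nb_mu = m / (1 - cfg.zi_pi)


def _zipf_weights(n: int, s: float, first: float | None = None) -> np.ndarray:
    w = (np.arange(1, n + 1, dtype=float)) ** (-s)
    w /= w.sum()
    if first is not None:
        w = w / w.sum() * (1 - first)
        w = np.r_[first, w[:-1] / w[:-1].sum() * (1 - first)]
    return w / w.sum()


def _group_mix(cfg: SimConfig) -> list[tuple[str, float, float]]:
    return [
        ("translocated", cfg.frac_translocated, cfg.mult_translocated),
        ("hhmm", cfg.frac_hhmm, cfg.mult_hhmm),
        ("other", 1 - cfg.frac_translocated - cfg.frac_hhmm, 1.0),
    ]


def _class_prob(group: str, pheno: str) -> tuple[float, float, float]:
    key = "translocated" if group == "translocated" else "other"
    return _CLASS_PROBS[(key, pheno)]


def _catalog_weights(cfg: SimConfig) -> dict[str, np.ndarray]:
    return {
        "IGH": _zipf_weights(cfg.n_hot_igh, cfg.zipf_exponent, cfg.first_weight_igh),
        "IGK": _zipf_weights(cfg.n_hot_igk, cfg.zipf_exponent, cfg.first_weight_igk),
        "IGL": _zipf_weights(cfg.n_hot_igl, cfg.zipf_exponent),
        "nonig": _zipf_weights(cfg.n_hot_nonig, cfg.zipf_exponent),
    }


def _occupancy(q: np.ndarray, n_samples: int) -> tuple[float, float]:
    """Expected #pairs hit by >=1 and >=2 samples given per-sample hit probs."""
    miss = (1 - q) ** n_samples
    one = n_samples * q * (1 - q) ** (n_samples - 1)
    return float((1 - miss).sum()), float((1 - miss - one).sum())


def _calibrate_ig_structure(cfg: SimConfig) -> None:
    n_grid = np.arange(0, 151)
    pmf = cfg.burden_pmf(150)
    groups = _group_mix(cfg)
    phenos = [("kappa", cfg.frac_kappa), ("lambda", 1 - cfg.frac_kappa)]
    weights = _catalog_weights(cfg)
    n_pat = cfg.n_patients
    t_total = n_pat * cfg.burden_mean

    def model(u: np.ndarray) -> dict:
        a, b, theta, ph_ig, ph_nig = u
        out: dict = {}
        p_hasig = 0.0
        e_n_hasig = 0.0
        e_ig = 0.0
        events_gp: dict[tuple[str, str], float] = {}
        w_by_group: dict[str, np.ndarray] = {}
        for g, pi_g, mult in groups:
            w = np.clip(mult * (a + b * n_grid), 0.0, 1.0)
            w[0] = 0.0
            w_by_group[g] = w
            hasig = w * (1 - (1 - theta) ** n_grid)
            p_hasig += pi_g * float((pmf * hasig).sum())
            e_n_hasig += pi_g * float((pmf * n_grid * hasig).sum())
            e_g = pi_g * float((pmf * w * n_grid).sum()) * theta
            e_ig += e_g
            for ph, pi_ph in phenos:
                events_gp[(g, ph)] = e_g * pi_ph
        out["p_hasig"] = p_hasig
        out["mean_with_ig"] = e_n_hasig / p_hasig if p_hasig > 0 else 0.0
        e_ig_total = n_pat * e_ig
        e_nonig_total = t_total - e_ig_total
        out["e_ig_total"] = e_ig_total

        # A hotspot draw whose pair is already used in the sample is
        # redirected to a fresh singleton event by the generator; the
        # expected number of redirected draws is (draws - distinct hits).
        used_ig = rec_ig = 0.0
        hot_kept_ig = 0.0
        for c_idx, cls in enumerate(("IGH", "IGK", "IGL")):
            wk = weights[cls]
            q = np.zeros_like(wk)
            for g, pi_g, _ in groups:
                w = w_by_group[g]
                for ph, pi_ph in phenos:
                    rho = theta * _class_prob(g, ph)[c_idx] * ph_ig * wk
                    inner = 1 - (1 - rho[None, :]) ** n_grid[:, None]
                    q += pi_g * pi_ph * (pmf * w) @ inner
            u1, u2 = _occupancy(q, n_pat)
            used_ig += u1
            rec_ig += u2
            hot_kept_ig += n_pat * float(q.sum())
        s_ig = e_ig_total * (1 - ph_ig) + max(0.0, e_ig_total * ph_ig - hot_kept_ig)

        wk = weights["nonig"]
        q = np.zeros_like(wk)
        for g, pi_g, _ in groups:
            w = w_by_group[g]
            rho_igtype = (1 - theta) * ph_nig * wk
            rho_plain = ph_nig * wk
            inner_ig = 1 - (1 - rho_igtype[None, :]) ** n_grid[:, None]
            inner_pl = 1 - (1 - rho_plain[None, :]) ** n_grid[:, None]
            q += pi_g * ((pmf * w) @ inner_ig + (pmf * (1 - w)) @ inner_pl)
        used_n, rec_n = _occupancy(q, n_pat)
        hot_kept_n = n_pat * float(q.sum())
        s_n = e_nonig_total * (1 - ph_nig) + max(
            0.0, e_nonig_total * ph_nig - hot_kept_n
        )

        unique = s_ig + used_ig + s_n + used_n
        out["ig_share"] = (s_ig + used_ig) / unique
        out["rec_share"] = (rec_ig + rec_n) / unique
        out["rec_nonig_share"] = rec_n / unique
        out["n_unique"] = unique
        return out

    targets = np.array(
        [
            cfg.target_pct_samples_ig,
            cfg.target_mean_with_ig,
            cfg.target_ig_share_unique,
            cfg.target_recurrent_share,
            cfg.target_recurrent_nonig_share,
        ]
    )
    scale = np.array([0.05, 0.5, 0.02, 0.02, 0.02])

    def residuals(u: np.ndarray) -> np.ndarray:
        m = model(u)
        vals = np.array(
            [
                m["p_hasig"],
                m["mean_with_ig"],
                m["ig_share"],
                m["rec_share"],
                m["rec_nonig_share"],
            ]
        )
        return (vals - targets) / scale

    x0 = np.array([0.20, 0.05, 0.50, 0.70, 0.70])
    sol = least_squares(
        residuals,
        x0,
        bounds=([-0.5, 0.0, 0.05, 0.01, 0.01], [0.9, 0.3, 0.95, 0.99, 0.99]),
        xtol=1e-12,
        ftol=1e-12,
    )
    achieved = model(sol.x)
    if np.abs(residuals(sol.x)).max() > 1.0:
        raise DataError(
            "infeasible configuration: calibration cannot reach the target "
            f"cohort statistics (achieved {achieved})"
        )
    cfg.ig_intercept, cfg.ig_slope, cfg.theta_ig, cfg.p_hot_ig, cfg.p_hot_nonig = (
        float(v) for v in sol.x
    )
    cfg.calibration_info = {k: float(v) for k, v in achieved.items()}


_PRESET_CACHE: dict[None, SimConfig] = {}


def myeloma_preset(seed: int = 0) -> SimConfig:
    """Configuration targeting the reference myeloma cohort statistics.

    Documented targets: mean burden 5.5 fusions per patient with 11.8%
    fusion-free patients; 47.3% of patients with at least one Ig fusion; mean
    burden 8.3 vs 3.8 for patients with vs without an Ig fusion (conditional
    on >=1 fusion); Ig fusions 36% of unique pairs; recurrent 28.8% and
    recurrent non-Ig 17.2% of unique pairs; cell-line mean burden 6.1.
    """
    if None not in _PRESET_CACHE:
        _PRESET_CACHE[None] = SimConfig().calibrate()
    cfg = dataclasses.replace(_PRESET_CACHE[None])
    cfg.calibration_info = dict(_PRESET_CACHE[None].calibration_info)
    cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _build_annotation(rng: np.random.Generator) -> tuple[GeneAnnotation, GeneFamilyTable]:
    genes: list[GeneRecord] = []
    counter = 0
    for chrom, length, n_slots in _CHROM_TABLE:
        slot = length // n_slots
        names: dict[int, str] = {}
        special: list[str] = []
        if chrom == "chr14":
            special += _IGH_GENES
        if chrom == "chr2":
            special += _IGK_GENES
        if chrom == "chr22":
            special += _IGL_GENES
        special += _NAMED_GENES.get(chrom, [])
        for fam, fam_chrom in _FAMILY_CHROM.items():
            if fam_chrom == chrom:
                special += _FAMILY_GENES[fam]
        # spread the named genes over deterministic slots
        if special:
            step = max(1, n_slots // (len(special) + 1))
            for i, name in enumerate(special):
                names[(i + 1) * step % n_slots] = name
        for i in range(n_slots):
            if i in names:
                sym = names[i]
            else:
                counter += 1
                sym = f"GENE{counter:04d}"
            lo = i * slot
            max_len = min(6000, slot - 1200)
            glen = int(rng.integers(1500, max(1501, max_len)))
            offset = int(rng.integers(500, max(501, slot - glen - 500)))
            start = lo + offset + 1
            genes.append(
                GeneRecord(
                    symbol=sym,
                    chrom=chrom,
                    start=start,
                    end=start + glen - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                    ig_class=ig_class_for_symbol(sym),
                )
            )
    annotation = GeneAnnotation(
        genes,
        chrom_lengths={c: l for c, l, _ in _CHROM_TABLE},
        aliases=dict(_ALIASES),
    )
    families = GeneFamilyTable(
        {g: {fam} for fam, members in _FAMILY_GENES.items() for g in members}
    )
    return annotation, families


@dataclass(frozen=True)
class _HotspotPair:
    gene5: str
    gene3: str
    bp5: int
    bp3: int


def _gene_bp(rng: np.random.Generator, rec: GeneRecord) -> int:
    return int(rng.integers(rec.start + 60, rec.end - 60))


def _build_catalogs(
    cfg: SimConfig, annotation: GeneAnnotation, families: GeneFamilyTable, rng: np.random.Generator
) -> dict[str, list[_HotspotPair]]:
    all_genes = list(annotation.genes.values())
    non_ig = [g for g in all_genes if not g.is_ig and not families.families(g.symbol)]
    chr19_genes = [g for g in non_ig if g.chrom == "chr19"]
    named = [
        annotation.genes[n]
        for ns in _NAMED_GENES.values()
        for n in ns
        if n != "IGHMBP2"
    ]
    # hotspot partner pool: named genes, extra chr19 genes, random others
    pool = list(
        dict.fromkeys(
            named
            + list(rng.choice(chr19_genes, size=20, replace=False))
            + list(rng.choice(non_ig, size=60, replace=False))
        )
    )

    ig_genes = {
        "IGH": [annotation.genes[s] for s in _IGH_GENES],
        "IGK": [annotation.genes[s] for s in _IGK_GENES],
        "IGL": [annotation.genes[s] for s in _IGL_GENES],
    }

    def make_pair(ig_rec: GeneRecord, partner: GeneRecord, ig_first: bool) -> _HotspotPair:
        g5, g3 = (ig_rec, partner) if ig_first else (partner, ig_rec)
        return _HotspotPair(g5.symbol, g3.symbol, _gene_bp(rng, g5), _gene_bp(rng, g3))

    catalogs: dict[str, list[_HotspotPair]] = {}
    seen: set[tuple[str, str]] = set()
    firsts = {
        "IGH": make_pair(annotation.genes["IGHM"], annotation.genes["NSD2"], True),
        "IGK": make_pair(annotation.genes["IGKC"], annotation.genes["B2M"], False),
    }
    for cls, n_hot in (("IGH", cfg.n_hot_igh), ("IGK", cfg.n_hot_igk), ("IGL", cfg.n_hot_igl)):
        entries: list[_HotspotPair] = []
        if cls in firsts:
            entries.append(firsts[cls])
            seen.add((entries[0].gene5, entries[0].gene3))
        while len(entries) < n_hot:
            ig_rec = pool_choice(rng, ig_genes[cls])
            partner = pool_choice(rng, pool)
            pair = make_pair(ig_rec, partner, rng.random() < 0.5)
            key = (pair.gene5, pair.gene3)
            if key in seen:
                continue
            seen.add(key)
            entries.append(pair)
        catalogs[cls] = entries

    entries = []
    tpm4, isyna1 = annotation.genes["TPM4"], annotation.genes["ISYNA1"]
    first = _HotspotPair(
        tpm4.symbol, isyna1.symbol, _gene_bp(rng, tpm4), _gene_bp(rng, isyna1)
    )
    entries.append(first)
    seen.add((first.gene5, first.gene3))
    while len(entries) < cfg.n_hot_nonig:
        if rng.random() < 0.5:
            # same-chromosome (read-through-like), chr19-weighted
            src = chr19_genes if rng.random() < 0.55 else non_ig
            g5 = pool_choice(rng, src)
            same = [g for g in non_ig if g.chrom == g5.chrom and g.symbol != g5.symbol]
            g3 = pool_choice(rng, same)
        else:
            g5 = pool_choice(rng, pool)
            g3 = pool_choice(rng, pool)
        if g5.symbol == g3.symbol or families.shared(g5.symbol, g3.symbol):
            continue
        key = (g5.symbol, g3.symbol)
        if key in seen:
            continue
        seen.add(key)
        entries.append(
            _HotspotPair(g5.symbol, g3.symbol, _gene_bp(rng, g5), _gene_bp(rng, g3))
        )
    catalogs["nonig"] = entries
    return catalogs


def pool_choice(rng: np.random.Generator, seq: Sequence):
    return seq[int(rng.integers(0, len(seq)))]


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Ground truth: one record per planted report row plus expression shifts."""

    records: list[dict] = field(default_factory=list)
    expression_shift: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)

    def pairs(self, sample_id: str, labels: Sequence[str]) -> set[tuple[str, str]]:
        return {
            (r["gene5"], r["gene3"])
            for r in self.records
            if r["sample_id"] == sample_id and r["label"] in labels
        }

    def true_pairs(self, sample_id: str) -> set[tuple[str, str]]:
        return self.pairs(sample_id, (TRUE, HOMOLOGY_DECOY))


@dataclass
class _Event:
    sample_id: str
    gene5: GeneRecord
    gene3: GeneRecord
    bp5: int
    bp3: int
    label: str
    jp_a: int
    jp_b: int
    is_ig: bool = False
    ig_class: str = "none"


class SimulatedCohort:
    """In-memory simulated study; files are written on demand.

    ``reports_a``/``reports_b`` hold the raw (pre-collapse) normalised calls
    per sample. ``reference`` is built lazily (deterministically from the
    seed) because only homology scoring needs sequence.
    """

    def __init__(
        self,
        config: SimConfig,
        annotation: GeneAnnotation,
        families: GeneFamilyTable,
        reports_a: dict[str, list[FusionCall]],
        reports_b: dict[str, list[FusionCall]],
        meta: dict[str, SampleMeta],
        expression: pd.DataFrame,
        truth: SimTruth,
        ref_seed: np.random.SeedSequence,
        decoy_plan: list[tuple],
    ) -> None:
        self.config = config
        self.annotation = annotation
        self.families = families
        self.reports_a = reports_a
        self.reports_b = reports_b
        self.meta = meta
        self.expression = expression
        self.truth = truth
        self._ref_seed = ref_seed
        self._decoy_plan = decoy_plan
        self._reference: dict[str, str] | None = None

    # -- reference ---------------------------------------------------------

    @property
    def reference(self) -> dict[str, str]:
        """Toy genome sequence with planted flank-homology decoys."""
        if self._reference is None:
            self._reference = self._build_reference()
        return self._reference

    def _build_reference(self) -> dict[str, str]:
        rng = np.random.default_rng(self._ref_seed)
        bases = np.frombuffer(b"ACGT", dtype="S1")
        seqs: dict[str, np.ndarray] = {}
        for chrom, length in self.annotation.chrom_lengths.items():
            seqs[chrom] = bases[rng.integers(0, 4, size=length)].copy()
        comp = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G byte codes

        def window(chrom: str, bp: int, strand: str, flank: int) -> np.ndarray:
            # flank window covering [before, after] in transcription order
            if strand == "+":
                return seqs[chrom][bp - flank : bp + flank]
            w = seqs[chrom][bp - flank : bp + flank][::-1]
            return np.frombuffer(
                bytes(comp[b] for b in w.tobytes()), dtype="S1"
            ).copy()

        flank = 20
        for chrom5, bp5, strand5, chrom3, bp3, strand3 in self._decoy_plan:
            src = window(chrom5, bp5, strand5, flank).copy()
            # two mismatches keep the homology below identity but far above
            # the unrelated-flank background
            for pos in (7, 29):
                cur = src[pos]
                src[pos] = bases[(np.flatnonzero(bases == cur)[0] + 1) % 4]
            if strand3 == "+":
                seqs[chrom3][bp3 - flank : bp3 + flank] = src
            else:
                rc = np.frombuffer(
                    bytes(comp[b] for b in src[::-1].tobytes()), dtype="S1"
                )
                seqs[chrom3][bp3 - flank : bp3 + flank] = rc
        return {c: a.tobytes().decode() for c, a in seqs.items()}

    # -- pipeline-ready views ---------------------------------------------

    def reports(self) -> dict[str, tuple[list[FusionCall], list[FusionCall]]]:
        """Collapsed per-sample call lists, ready for consensus intersection."""
        return {
            s: (collapse_calls(self.reports_a[s]), collapse_calls(self.reports_b[s]))
            for s in self.meta
        }

    # -- file emission ------------------------------------------------------

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gene_annotation(self.annotation, outdir / "annotation.gff3")
        write_gene_families(self.families, outdir / "gene_families.tsv")
        write_sample_metadata(self.meta, outdir / "metadata.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        with open(outdir / "reference.fa", "w") as fh:
            for chrom, seq in self.reference.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        reports_dir = outdir / "reports"
        reports_dir.mkdir(exist_ok=True)
        for sample in self.meta:
            self._write_tophat(
                self.reports_a[sample], reports_dir / f"{sample}.tophat.tsv"
            )
            self._write_mapsplice(
                self.reports_b[sample], reports_dir / f"{sample}.mapsplice.tsv"
            )
        with open(outdir / "truth.json", "w") as fh:
            json.dump(
                {
                    "records": self.truth.records,
                    "expression_shift": self.truth.expression_shift,
                },
                fh,
                indent=1,
            )

    @staticmethod
    def _write_tophat(calls: list[FusionCall], path: Path) -> None:
        d = TOPHAT_DIALECT
        cols = [
            d.gene5_col, d.chrom5_col, d.bp5_col, d.strand5_col,
            d.gene3_col, d.chrom3_col, d.bp3_col, d.strand3_col,
            d.junction_cols[0],
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for c in calls:
                fh.write(
                    f"{c.gene5}\t{c.chrom5}\t{c.bp5 - 1}\t{c.strand5}\t"
                    f"{c.gene3}\t{c.chrom3}\t{c.bp3 - 1}\t{c.strand3}\t"
                    f"{c.junction_pairs}\n"
                )

    @staticmethod
    def _write_mapsplice(calls: list[FusionCall], path: Path) -> None:
        d = MAPSPLICE_DIALECT
        cols = [
            d.chrom_pair_col, d.bp5_col, d.bp3_col, d.strand_pair_col,
            d.junction_cols[0], d.junction_cols[1],
            d.gene5_col, d.gene3_col,
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for c in calls:
                chrom = f"{c.chrom5[3:]}~{c.chrom3[3:]}"
                multiple = c.junction_pairs // 3
                unique = c.junction_pairs - multiple
                fh.write(
                    f"{chrom}\t{c.bp5}\t{c.bp3}\t{c.strand5}{c.strand3}\t"
                    f"{multiple}\t{unique}\t{c.gene5}\t{c.gene3}\n"
                )


def _support(rng: np.random.Generator, cfg: SimConfig) -> int:
    extra = cfg.support_mean - 3
    return 3 + int(rng.negative_binomial(1.2, 1.2 / (1.2 + extra)))


def _sample_burden_patient(rng: np.random.Generator, cfg: SimConfig) -> int:
    if rng.random() < cfg.zi_pi:
        return 0
    r = cfg.burden_dispersion
    return int(rng.negative_binomial(r, r / (r + cfg.nb_mu)))


def _sample_burden_cell_line(rng: np.random.Generator, cfg: SimConfig) -> int:
    r = cfg.cell_line_dispersion
    p = r / (r + cfg.cell_line_burden_mean)
    while True:
        n = int(rng.negative_binomial(r, p))
        if n >= 1:
            return n


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full synthetic study from a (calibrated) configuration.

    Identical configurations produce identical cohorts (and byte-identical
    files); true events appear in both callers' reports with jittered
    breakpoints on the MapSplice-style side, caller-specific false positives
    in exactly one.
    """
    cfg = config
    if not cfg.calibrated:
        cfg = dataclasses.replace(config)
        cfg.calibrate()
    ss = np.random.SeedSequence(cfg.seed)
    genome_seed, cohort_seed, ref_seed, expr_seed = ss.spawn(4)
    genome_rng = np.random.default_rng(genome_seed)
    rng = np.random.default_rng(cohort_seed)

    annotation, families = _build_annotation(genome_rng)
    catalogs = _build_catalogs(cfg, annotation, families, genome_rng)
    weights = _catalog_weights(cfg)
    all_genes = list(annotation.genes.values())
    non_ig = [g for g in all_genes if not g.is_ig]
    non_ig_clean = [g for g in non_ig if not families.families(g.symbol)]
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in non_ig_clean:
        by_chrom.setdefault(g.chrom, []).append(g)
    chroms = [c for c in by_chrom if len(by_chrom[c]) >= 2]
    chrom_w = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    ig_genes = {
        "IGH": [annotation.genes[s] for s in _IGH_GENES],
        "IGK": [annotation.genes[s] for s in _IGK_GENES],
        "IGL": [annotation.genes[s] for s in _IGL_GENES],
    }
    fam_pool = {
        fam: [annotation.genes[s] for s in members]
        for fam, members in _FAMILY_GENES.items()
    }

    truth = SimTruth()
    decoy_plan: list[tuple] = []
    reports_a: dict[str, list[FusionCall]] = {}
    reports_b: dict[str, list[FusionCall]] = {}
    meta: dict[str, SampleMeta] = {}
    patient_burden: dict[str, int] = {}

    def fresh_ig_event(cls: str, used: set) -> tuple[GeneRecord, GeneRecord, int, int] | None:
        ig_rec = pool_choice(rng, ig_genes[cls])
        partner = pool_choice(rng, non_ig_clean)
        ig_first = rng.random() < 0.5
        g5, g3 = (ig_rec, partner) if ig_first else (partner, ig_rec)
        if (g5.symbol, g3.symbol) in used:
            return None
        return g5, g3, _gene_bp(rng, g5), _gene_bp(rng, g3)

    def fresh_nonig_event(used: set) -> tuple[GeneRecord, GeneRecord, int, int] | None:
        if rng.random() < cfg.same_chr_fraction:
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_w))]
            pair = rng.choice(len(by_chrom[chrom]), size=2, replace=False)
            g5, g3 = by_chrom[chrom][pair[0]], by_chrom[chrom][pair[1]]
        else:
            g5 = pool_choice(rng, non_ig_clean)
            g3 = pool_choice(rng, non_ig_clean)
        if g5.symbol == g3.symbol or (g5.symbol, g3.symbol) in used:
            return None
        if families.shared(g5.symbol, g3.symbol):
            return None
        return g5, g3, _gene_bp(rng, g5), _gene_bp(rng, g3)

    def hotspot_event(cls: str, used: set) -> tuple[GeneRecord, GeneRecord, int, int] | None:
        entries = catalogs[cls]
        k = int(rng.choice(len(entries), p=weights[cls]))
        e = entries[k]
        if (e.gene5, e.gene3) in used:
            return None
        return (
            annotation.genes[e.gene5],
            annotation.genes[e.gene3],
            e.bp5,
            e.bp3,
        )

    def generate_sample(
        sample_id: str,
        n_true: int,
        ig_type: bool,
        theta: float,
        p_hot_ig: float,
        p_hot_nonig: float,
        group: str,
        pheno: str,
    ) -> None:
        used: set[tuple[str, str]] = set()
        events: list[_Event] = []
        cls_p = np.array(_class_prob(group, pheno))
        for _ in range(n_true):
            is_ig = ig_type and rng.random() < theta
            placed = None
            label = TRUE
            cls = "none"
            if is_ig:
                cls = ("IGH", "IGK", "IGL")[int(rng.choice(3, p=cls_p))]
                if rng.random() < p_hot_ig:
                    # a collision (pair already used in this sample) falls
                    # through to a fresh singleton event of the same class
                    placed = hotspot_event(cls, used)
            else:
                if rng.random() < p_hot_nonig:
                    placed = hotspot_event("nonig", used)
            if placed is None:
                for _attempt in range(200):
                    placed = (
                        fresh_ig_event(cls, used)
                        if is_ig
                        else fresh_nonig_event(used)
                    )
                    if placed is not None:
                        break
                if placed is None:  # pragma: no cover - pathological configs
                    raise DataError("could not place event; gene pool too small")
                if rng.random() < cfg.homology_decoy_frac:
                    label = HOMOLOGY_DECOY
            g5, g3, bp5, bp3 = placed
            used.add((g5.symbol, g3.symbol))
            events.append(
                _Event(
                    sample_id, g5, g3, bp5, bp3, label,
                    _support(rng, cfg), _support(rng, cfg),
                    is_ig=is_ig, ig_class=cls if is_ig else "none",
                )
            )
            if label == HOMOLOGY_DECOY:
                decoy_plan.append(
                    (g5.chrom, bp5, g5.strand, g3.chrom, bp3, g3.strand)
                )

        for _ in range(rng.poisson(cfg.family_decoy_rate)):
            fam = pool_choice(rng, list(fam_pool))
            pair = rng.choice(len(fam_pool[fam]), size=2, replace=False)
            g5, g3 = fam_pool[fam][pair[0]], fam_pool[fam][pair[1]]
            if (g5.symbol, g3.symbol) in used:
                continue
            used.add((g5.symbol, g3.symbol))
            events.append(
                _Event(
                    sample_id, g5, g3, _gene_bp(rng, g5), _gene_bp(rng, g3),
                    FAMILY_DECOY, _support(rng, cfg), _support(rng, cfg),
                )
            )

        for _ in range(rng.poisson(cfg.low_support_rate)):
            placed = fresh_nonig_event(used)
            if placed is None:
                continue
            g5, g3, bp5, bp3 = placed
            used.add((g5.symbol, g3.symbol))
            events.append(
                _Event(
                    sample_id, g5, g3, bp5, bp3, LOW_SUPPORT,
                    int(rng.integers(0, 3)), int(rng.integers(0, 8)),
                )
            )

        fps: list[_Event] = []
        for label, rate in ((FP_A, cfg.fp_rate_a), (FP_B, cfg.fp_rate_b)):
            for _ in range(rng.poisson(rate)):
                placed = fresh_nonig_event(used)
                if placed is None:
                    continue
                g5, g3, bp5, bp3 = placed
                used.add((g5.symbol, g3.symbol))
                fps.append(
                    _Event(
                        sample_id, g5, g3, bp5, bp3, label,
                        int(rng.integers(1, 30)), int(rng.integers(1, 30)),
                    )
                )

        calls_a: list[FusionCall] = []
        calls_b: list[FusionCall] = []

        def jitter(bp: int, rec: GeneRecord) -> int:
            j = int(round(rng.normal(0, cfg.breakpoint_jitter_sd)))
            return int(np.clip(bp + j, rec.start + 25, rec.end - 25))

        def call(ev: _Event, caller: Caller, jp: int, jittered: bool) -> FusionCall:
            bp5 = jitter(ev.bp5, ev.gene5) if jittered else ev.bp5
            bp3 = jitter(ev.bp3, ev.gene3) if jittered else ev.bp3
            return FusionCall(
                sample_id=ev.sample_id,
                caller=caller,
                gene5=ev.gene5.symbol,
                gene3=ev.gene3.symbol,
                chrom5=ev.gene5.chrom,
                chrom3=ev.gene3.chrom,
                bp5=bp5,
                bp3=bp3,
                strand5=ev.gene5.strand,
                strand3=ev.gene3.strand,
                junction_pairs=jp,
            )

        for ev in events:
            calls_a.append(call(ev, Caller.A, ev.jp_a, jittered=False))
            calls_b.append(call(ev, Caller.B, ev.jp_b, jittered=True))
            if ev.label in (TRUE, HOMOLOGY_DECOY) and rng.random() < cfg.duplicate_row_rate:
                # a second row for the same pair with weaker support; the
                # reader's collapse step must keep the stronger row
                calls_a.append(
                    call(
                        dataclasses.replace(ev, bp5=jitter(ev.bp5, ev.gene5)),
                        Caller.A,
                        max(1, ev.jp_a - 2),
                        jittered=False,
                    )
                )
        for ev in fps:
            if ev.label == FP_A:
                calls_a.append(call(ev, Caller.A, ev.jp_a, jittered=False))
            else:
                calls_b.append(call(ev, Caller.B, ev.jp_b, jittered=True))

        reports_a[sample_id] = calls_a
        reports_b[sample_id] = calls_b
        for ev in events + fps:
            truth.records.append(
                {
                    "sample_id": sample_id,
                    "gene5": ev.gene5.symbol,
                    "gene3": ev.gene3.symbol,
                    "label": ev.label,
                    "is_ig": ev.is_ig,
                    "ig_class": ev.ig_class,
                    "junction_pairs_a": ev.jp_a,
                    "junction_pairs_b": ev.jp_b,
                }
            )

    # -- patients -----------------------------------------------------------
    group_names, group_probs, group_mults = zip(
        *[(g, p, m) for g, p, m in _group_mix(cfg)]
    )
    burdens = []
    for i in range(cfg.n_patients):
        sample_id = f"P{i + 1:03d}"
        group = group_names[int(rng.choice(len(group_names), p=np.array(group_probs)))]
        pheno = "kappa" if rng.random() < cfg.frac_kappa else "lambda"
        n_true = _sample_burden_patient(rng, cfg)
        mult = dict(zip(group_names, group_mults))[group]
        w = float(np.clip(mult * (cfg.ig_intercept + cfg.ig_slope * n_true), 0, 1))
        ig_type = n_true > 0 and rng.random() < w
        generate_sample(
            sample_id, n_true, ig_type, cfg.theta_ig, cfg.p_hot_ig,
            cfg.p_hot_nonig, group, pheno,
        )
        meta[sample_id] = SampleMeta(
            sample_id=sample_id,
            population="patient",
            light_chain=pheno,
            ploidy_group="high_hyperdiploid" if group == "hhmm" else "other",
            fish_translocation=group == "translocated",
            age=None,  # filled below from the burden copula
        )
        patient_burden[sample_id] = n_true
        burdens.append(n_true)

    # ages correlated with burden through a Gaussian copula
    n = np.array(burdens, dtype=float)
    ranks = sps.rankdata(n + rng.uniform(0, 0.5, size=n.size))  # random tie-break
    z_burden = sps.norm.ppf((ranks - 0.5) / n.size)
    z_age = cfg.age_burden_rho * z_burden + np.sqrt(
        1 - cfg.age_burden_rho**2
    ) * rng.standard_normal(n.size)
    ages = np.clip(cfg.age_mean + cfg.age_sd * z_age, 30, 65)
    for sample_id, age in zip(list(meta), ages):
        meta[sample_id].age = float(round(age, 1))

    # -- cell lines ---------------------------------------------------------
    for i in range(cfg.n_cell_lines):
        sample_id = f"CL{i + 1:02d}"
        n_true = _sample_burden_cell_line(rng, cfg)
        ig_type = rng.random() < cfg.cell_line_ig_type_prob
        pheno = "kappa" if rng.random() < 0.6 else "lambda"
        generate_sample(
            sample_id, n_true, ig_type, cfg.cell_line_theta,
            cfg.cell_line_p_hot_ig, cfg.cell_line_p_hot_nonig,
            "translocated", pheno,
        )
        meta[sample_id] = SampleMeta(
            sample_id=sample_id, population="cell_line", light_chain=pheno
        )

    # -- expression ---------------------------------------------------------
    expr_rng = np.random.default_rng(expr_seed)
    fused_genes: dict[str, set] = {}
    for r in truth.records:
        if r["label"] in (TRUE, HOMOLOGY_DECOY):
            for g in (r["gene5"], r["gene3"]):
                fused_genes.setdefault(g, set()).add(r["sample_id"])
    catalog_genes = {
        g for entries in catalogs.values() for e in entries for g in (e.gene5, e.gene3)
    }
    background = [
        g.symbol
        for g in expr_rng.choice(
            [g for g in all_genes if g.symbol not in catalog_genes],
            size=cfg.n_background_genes,
            replace=False,
        )
    ]
    expr_index = sorted(catalog_genes | set(fused_genes) | set(background))
    samples = list(meta)
    baseline = expr_rng.uniform(4, 10, size=len(expr_index))
    mat = baseline[:, None] + expr_rng.normal(
        0, cfg.expression_noise_sd, size=(len(expr_index), len(samples))
    )
    expression = pd.DataFrame(mat, index=expr_index, columns=samples)
    for gene, fused in fused_genes.items():
        effect = 4.0 if gene == "NSD2" else cfg.expression_effect
        cols = [s for s in fused if s in expression.columns]
        expression.loc[gene, cols] += effect
        truth.expression_shift[gene] = effect
    expression = expression.round(4)

    return SimulatedCohort(
        config=cfg,
        annotation=annotation,
        families=families,
        reports_a=reports_a,
        reports_b=reports_b,
        meta=meta,
        expression=expression,
        truth=truth,
        ref_seed=ref_seed,
        decoy_plan=decoy_plan,
    )
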