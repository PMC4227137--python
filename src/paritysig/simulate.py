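"""Synthetic microarray cohorts with a planted parity signature.

The generator emulates the statistical structure the analysis pipeline
assumes: a training cohort of normal breast tissue from parous and
nulliparous women in which a block of signature genes is additively
upregulated (on the log2 scale) in parous samples, and a paired test cohort
(one cancer-adjacent normal and one tumor sample per subject, with tumor ER
status) in which that planted signal is attenuated tissue- and ER-status-
dependently. Defaults mirror the study conditions: 130 training samples
(76 parous / 54 nulliparous), 150 test subjects (79% parous, 78% ER+), a
251-gene upregulated block with linear fold changes of roughly 1.1-1.9, and
10,000 background genes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .signature import GeneSignature, SignatureEntry


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    log2 fold changes of signature genes are drawn uniformly from
    ``log2fc_range``; noise is i.i.d. Gaussian on the log2 scale with standard
    deviation ``noise_sd`` (optionally with block-correlated structure via
    ``block_correlation``). Attenuation multipliers scale the planted parous
    shift in the test cohort: per tissue for ER+ subjects, and jointly (both
    tissues) for ER- subjects.
    """

    n_genes: int = 10_000
    n_signature_genes: int = 251
    train_n_parous: int = 76
    train_n_nulliparous: int = 54
    test_n_subjects: int = 150
    test_parous_fraction: float = 0.79
    test_er_positive_fraction: float = 0.78
    log2fc_range: tuple[float, float] = (0.2, 0.9)
    noise_sd: float = 0.5
    attenuation_adjacent_erpos: float = 0.6
    attenuation_tumor_erpos: float = 0.4
    attenuation_erneg: float = 0.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    block_correlation: float = 0.0
    block_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_signature_genes <= self.n_genes:
            raise ValueError("need 1 <= n_signature_genes <= n_genes")
        for field in ("train_n_parous", "train_n_nulliparous", "test_n_subjects"):
            if getattr(self, field) < 1:
                raise ValueError(f"{field} must be >= 1")
        for field in ("test_parous_fraction", "test_er_positive_fraction"):
            if not 0.0 <= getattr(self, field) <= 1.0:
                raise ValueError(f"{field} must lie in [0, 1]")
        lo, hi = self.log2fc_range
        if lo < 0 or hi < lo:
            raise ValueError("log2fc_range must satisfy 0 <= low <= high")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for field in (
            "attenuation_adjacent_erpos",
            "attenuation_tumor_erpos",
            "attenuation_erneg",
        ):
            if not 0.0 <= getattr(self, field) <= 1.0:
                raise ValueError(f"{field} must lie in [0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "log2fc_range" in raw:
            raw["log2fc_range"] = tuple(raw["log2fc_range"])
        return cls(**raw)


def _gene_names(n: int) -> list[str]:
    return [f"G{i + 1:05d}" for i in range(n)]


def _noise(rng: np.random.Generator, cfg: SyntheticConfig, n_samples: int) -> np.ndarray:
    """Gene x sample noise; optionally correlated within consecutive gene blocks."""
    eps = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, n_samples))
    rho = cfg.block_correlation
    if rho > 0:
        n_blocks = int(np.ceil(cfg.n_genes / cfg.block_size))
        shared = rng.normal(0.0, cfg.noise_sd, size=(n_blocks, n_samples))
        shared_full = np.repeat(shared, cfg.block_size, axis=0)[: cfg.n_genes]
        eps = np.sqrt(1.0 - rho) * eps + np.sqrt(rho) * shared_full
    return eps


def simulate_training_cohort(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GeneSignature]:
    """Simulate the discovery cohort (normal tissue, parous vs nulliparous).

    Background genes share the same distribution in both groups; each
    signature gene receives an additive log2 shift, drawn uniformly from
    ``cfg.log2fc_range``, in parous samples only.

    Returns the genes x samples matrix, the sample annotation and the
    ground-truth signature (direction ``up`` with the drawn linear fold
    changes).
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_names(cfg.n_genes)
    sig_idx = np.sort(rng.choice(cfg.n_genes, size=cfg.n_signature_genes, replace=False))
    shifts = rng.uniform(*cfg.log2fc_range, size=cfg.n_signature_genes)
    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    n_par, n_nul = cfg.train_n_parous, cfg.train_n_nulliparous
    n = n_par + n_nul
    values = baselines[:, None] + _noise(rng, cfg, n)
    parity = np.array(["parous"] * n_par + ["nulliparous"] * n_nul)
    values[np.ix_(sig_idx, np.arange(n_par))] += shifts[:, None]

    sample_ids = [f"TR{i + 1:03d}" for i in range(n)]
    premeno = rng.random(n) < 0.65
    afb = np.where(parity == "parous", np.clip(rng.normal(24.0, 4.0, n), 16, 42), np.nan)
    ysb = np.where(parity == "parous", np.clip(rng.normal(12.0, 8.0, n), 0, None), np.nan)
    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": sample_ids,
            "parity": parity,
            "tissue": "normal",
            "er_status": "unknown",
            "menopausal": np.where(premeno, "pre", "post"),
            "age_first_birth_years": afb,
            "years_since_last_birth": ysb,
        },
        index=sample_ids,
    )
    ann.index.name = None
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    signature = GeneSignature(
        "synthetic_parity_signature",
        tuple(
            SignatureEntry(genes[g], "up", float(2.0 ** s))
            for g, s in zip(sig_idx, shifts)
        ),
    )
    return matrix, ann, signature


def simulate_test_cohort(
    cfg: SyntheticConfig, sig: GeneSignature
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the paired test cohort (adjacent normal + tumor per subject).

    Parity and ER status are Bernoulli draws with the configured fractions.
    Parous subjects receive the signature's log2 shift scaled by
    ``attenuation_adjacent_erpos`` / ``attenuation_tumor_erpos`` when ER+,
    and by ``attenuation_erneg`` in both tissues when ER-.
    """
    if len(sig) == 0:
        raise ValueError("signature must be nonempty")
    if not sig.has_fold_changes():
        raise ValueError("test-cohort simulation needs signature fold changes")
    rng = np.random.default_rng(cfg.seed + 1)
    genes = _gene_names(cfg.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    sig_idx = np.array([gene_pos[e.gene] for e in sig.entries if e.gene in gene_pos])
    if sig_idx.size == 0:
        raise ValueError("no signature gene is present in the simulated gene space")
    shifts = np.array(
        [np.log2(e.fold_change) for e in sig.entries if e.gene in gene_pos]
    )

    n_subj = cfg.test_n_subjects
    parous = rng.random(n_subj) < cfg.test_parous_fraction
    er_pos = rng.random(n_subj) < cfg.test_er_positive_fraction
    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    subj_ids = [f"SUBJ{i + 1:03d}" for i in range(n_subj)]
    sample_ids, rows = [], []
    for i, subj in enumerate(subj_ids):
        for tissue, tag in (("adjacent_normal", "AN"), ("tumor", "TU")):
            sample_ids.append(f"{subj}_{tag}")
            rows.append((subj, tissue, i))
    n_samples = len(sample_ids)
    values = baselines[:, None] + _noise(rng, cfg, n_samples)

    atten = np.empty(n_samples)
    for j, (_, tissue, i) in enumerate(rows):
        if not parous[i]:
            atten[j] = 0.0
        elif not er_pos[i]:
            atten[j] = cfg.attenuation_erneg
        elif tissue == "adjacent_normal":
            atten[j] = cfg.attenuation_adjacent_erpos
        else:
            atten[j] = cfg.attenuation_tumor_erpos
    values[sig_idx, :] += shifts[:, None] * atten[None, :]

    premeno = rng.random(n_subj) < 0.27
    afb_subj = np.where(parous, np.clip(rng.normal(24.0, 4.0, n_subj), 16, 42), np.nan)
    ysb_subj = np.where(parous, np.clip(rng.normal(20.0, 9.0, n_subj), 0, None), np.nan)
    ann = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [r[0] for r in rows],
            "parity": [("parous" if parous[r[2]] else "nulliparous") for r in rows],
            "tissue": [r[1] for r in rows],
            "er_status": [("positive" if er_pos[r[2]] else "negative") for r in rows],
            "menopausal": [("pre" if premeno[r[2]] else "post") for r in rows],
            "age_first_birth_years": [afb_subj[r[2]] for r in rows],
            "years_since_last_birth": [ysb_subj[r[2]] for r in rows],
        },
        index=sample_ids,
    )
    ann.index.name = None
    matrix = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return matrix, ann
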