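"""Orchestration: discover a signature, then test its transfer per stratum.

``run_discovery`` runs SAM on a training cohort, extracts the upregulated
signature and scores the hierarchical-clustering parity accuracy.
``run_transfer`` evaluates a signature in a paired test cohort for each
tissue x stratum combination: GSEA enrichment with permutation FWER,
Creighton calls, and the 2x2 call-vs-parity association. Strata are
analysed marginally (one variable at a time); parity-history strata
restrict the parous group only, ER and menopausal strata restrict all
samples. Small strata (fewer than two samples per parity group) are skipped
with a logged reason rather than crashing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as psio
from .association import AssociationResult, ContingencyTable, associate
from .clustering import ClusterReport, cluster_samples, parity_accuracy
from .creighton import score_samples
from .errors import ZeroCellError
from .gsea import EnrichmentResult, permutation_fwer
from .preprocess import collapse_probes
from .sam import SamParams, SamResult, extract_signature, sam_fdr
from .signature import GeneSignature, align_signature
from .simulate import SyntheticConfig, simulate_test_cohort, simulate_training_cohort

logger = logging.getLogger(__name__)

DEFAULT_STRATA = ("all", "er_positive", "er_negative")
KNOWN_STRATA = DEFAULT_STRATA + (
    "age_first_birth_low",
    "age_first_birth_high",
    "years_since_birth_low",
    "years_since_birth_high",
    "premenopausal",
    "postmenopausal",
)


@dataclass
class AnalysisConfig:
    """Everything a full pipeline run needs; round-trips through YAML."""

    training_expression: str | None = None
    training_annotation: str | None = None
    test_expression: str | None = None
    test_annotation: str | None = None
    signature: str | None = None
    out_dir: str = "paritysig_out"
    seed: int = 0
    sam_n_permutations: int = 1000
    sam_target_fdr: float = 0.01
    sam_s0_mode: str = "percentile_auto"
    sam_s0_value: float = 0.0
    gsea_n_permutations: int = 1000
    gsea_weight_p: float = 1.0
    fwer_threshold: float = 0.15
    creighton_mode: str = "median_fold_change"
    min_match_fraction: float = 0.5
    strata: tuple[str, ...] = DEFAULT_STRATA
    age_first_birth_cut: float = 25.0
    years_since_last_birth_cut: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.fwer_threshold < 1:
            raise ValueError("fwer_threshold must lie in (0, 1)")
        if self.age_first_birth_cut <= 0 or self.years_since_last_birth_cut <= 0:
            raise ValueError("stratification cutpoints must be positive")
        self.strata = tuple(self.strata)
        unknown = set(self.strata) - set(KNOWN_STRATA)
        if unknown:
            raise ValueError(f"unknown strata {sorted(unknown)}; allowed {KNOWN_STRATA}")

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # output location must not change the analysis hash
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)

    def _require_files(self, *fields: str) -> None:
        for name in fields:
            path = getattr(self, name)
            if path is None:
                raise ValueError(f"config field {name!r} is required for this command")
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name}: no such file {path!r}")


@dataclass
class DiscoveryResult:
    signature: GeneSignature
    sam: SamResult
    clusters: ClusterReport | None
    parous_accuracy: float | None
    nulliparous_accuracy: float | None


@dataclass
class StratumAnalysis:
    tissue: str
    stratum: str
    n_parous: int
    n_nulliparous: int
    enrichment: EnrichmentResult | None = None
    creighton: pd.DataFrame | None = field(default=None, repr=False)
    association: AssociationResult | None = None
    association_note: str | None = None
    skipped_reason: str | None = None


def run_discovery(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    params: SamParams | None = None,
    signature_name: str = "parity_signature",
    cluster: bool = True,
) -> DiscoveryResult:
    """SAM differential expression plus the clustering accuracy report."""
    matrix = collapse_probes(matrix)
    labels = psio.parity_labels(ann, matrix.columns)
    result = sam_fdr(matrix, labels, params)
    sig = extract_signature(result, signature_name)
    clusters = par_acc = nul_acc = None
    if cluster and len(sig) >= 2:
        clusters = cluster_samples(matrix.loc[sig.genes])
        par_acc, nul_acc = parity_accuracy(clusters, ann)
    elif cluster:
        logger.warning("signature too small to cluster (%d genes)", len(sig))
    return DiscoveryResult(sig, result, clusters, par_acc, nul_acc)


def _stratum_mask(ann: pd.DataFrame, stratum: str, cfg: AnalysisConfig) -> np.ndarray:
    """Boolean sample mask for one named stratum.

    ER and menopausal strata filter every sample (unknowns dropped);
    parity-history strata filter parous samples only, keeping all
    nulliparous samples as the comparison group.
    """
    parous = ann["parity"].to_numpy() == "parous"
    if stratum == "all":
        return np.ones(len(ann), dtype=bool)
    if stratum == "er_positive":
        return ann["er_status"].to_numpy() == "positive"
    if stratum == "er_negative":
        return ann["er_status"].to_numpy() == "negative"
    if stratum == "premenopausal":
        return ann["menopausal"].to_numpy() == "pre"
    if stratum == "postmenopausal":
        return ann["menopausal"].to_numpy() == "post"
    afb = ann["age_first_birth_years"].to_numpy(dtype=float)
    ysb = ann["years_since_last_birth"].to_numpy(dtype=float)
    if stratum == "age_first_birth_low":
        return ~parous | (afb <= cfg.age_first_birth_cut)
    if stratum == "age_first_birth_high":
        return ~parous | (afb > cfg.age_first_birth_cut)
    if stratum == "years_since_birth_low":
        return ~parous | (ysb < cfg.years_since_last_birth_cut)
    if stratum == "years_since_birth_high":
        return ~parous | (ysb >= cfg.years_since_last_birth_cut)
    raise ValueError(f"unknown stratum {stratum!r}")


def run_transfer(
    matrix: pd.DataFrame,
    ann: pd.DataFrame,
    sig: GeneSignature,
    cfg: AnalysisConfig | None = None,
    seed: int | None = None,
) -> list[StratumAnalysis]:
    """Evaluate a signature in a paired test cohort, per tissue and stratum."""
    cfg = cfg or AnalysisConfig()
    seed = cfg.seed if seed is None else seed
    if len(sig) == 0:
        raise ValueError("cannot run transfer with an empty signature")
    matrix = collapse_probes(matrix)
    aligned, _ = align_signature(sig, matrix, cfg.min_match_fraction)
    analyses: list[StratumAnalysis] = []
    tissues = [t for t in ("adjacent_normal", "tumor", "normal")
               if t in set(ann["tissue"])]
    for t_i, tissue in enumerate(tissues):
        t_samples = ann.index[ann["tissue"] == tissue]
        t_samples = [s for s in t_samples if s in matrix.columns]
        t_matrix = matrix[t_samples]
        t_ann = ann.loc[t_samples]
        for s_i, stratum in enumerate(cfg.strata):
            mask = _stratum_mask(t_ann, stratum, cfg)
            sub_ann = t_ann.loc[mask]
            n_par = int((sub_ann["parity"] == "parous").sum())
            n_nul = int((sub_ann["parity"] == "nulliparous").sum())
            entry = StratumAnalysis(tissue, stratum, n_par, n_nul)
            if n_par < 2 or n_nul < 2:
                entry.skipped_reason = (
                    f"needs >= 2 samples per parity group (parous={n_par}, "
                    f"nulliparous={n_nul})"
                )
                logger.warning("skipping %s/%s: %s", tissue, stratum, entry.skipped_reason)
                analyses.append(entry)
                continue
            sub_matrix = t_matrix[sub_ann.index.tolist()]
            labels = sub_ann["parity"].to_numpy()
            entry.enrichment = permutation_fwer(
                sub_matrix,
                labels,
                aligned,
                n_permutations=cfg.gsea_n_permutations,
                seed=seed + 1000 * t_i + s_i,
                weight_p=cfg.gsea_weight_p,
            )
            scores = score_samples(
                sub_matrix, aligned, mode=cfg.creighton_mode,
                min_match_fraction=cfg.min_match_fraction,
            )
            entry.creighton = scores
            table = ContingencyTable.from_calls(scores["call"].to_numpy(), labels)
            try:
                entry.association = associate(table)
            except ZeroCellError as exc:
                entry.association_note = str(exc)
                logger.warning("%s/%s association: %s", tissue, stratum, exc)
            analyses.append(entry)
    return analyses


def transfer_summary(analyses: list[StratumAnalysis], fwer_threshold: float = 0.15) -> pd.DataFrame:
    """Flatten stratum analyses into a report table (Tables 3/4 layout)."""
    rows = []
    for a in analyses:
        row: dict[str, object] = {
            "tissue": a.tissue,
            "stratum": a.stratum,
            "n_parous": a.n_parous,
            "n_nulliparous": a.n_nulliparous,
            "skipped": a.skipped_reason or "",
        }
        if a.enrichment is not None:
            row.update(
                es=round(a.enrichment.es, 2),
                nes=round(a.enrichment.nes, 3),
                fwer_percent=int(round(a.enrichment.fwer * 100)),
                gsea_significant=bool(a.enrichment.fwer <= fwer_threshold),
            )
        if a.association is not None:
            r = a.association
            row.update(
                counts="/".join(str(v) for v in r.table.cells),
                odds_ratio=round(r.or_estimate, 2),
                ci_low=round(r.ci_low, 2),
                ci_high=round(r.ci_high, 2),
                p_value=r.p_value,
                test_used=r.test_used,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _write_json(payload: dict, path: str, meta: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({**meta, **payload}, fh, indent=2, default=str)
        fh.write("\n")


def run_pipeline(cfg: AnalysisConfig) -> dict:
    """File-level end-to-end run: discover (or load) a signature, transfer it.

    Writes the signature, the SAM table, the cluster report and the transfer
    summary under ``cfg.out_dir``; every output embeds the config hash and
    the RNG seed. Returns a dict of the key results.
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    meta = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    results: dict = {}

    if cfg.signature is not None:
        cfg._require_files("signature")
        sig = psio.read_signature(cfg.signature)
    else:
        cfg._require_files("training_expression", "training_annotation")
        train = psio.read_expression(cfg.training_expression)
        train_ann = psio.read_annotation(cfg.training_annotation)
        params = SamParams(
            s0_mode=cfg.sam_s0_mode,
            s0_value=cfg.sam_s0_value,
            n_permutations=cfg.sam_n_permutations,
            target_fdr=cfg.sam_target_fdr,
            seed=cfg.seed,
        )
        disc = run_discovery(train, train_ann, params)
        sig = disc.signature
        psio.write_signature(sig, os.path.join(cfg.out_dir, "signature.tsv"), metadata=meta)
        with open(os.path.join(cfg.out_dir, "sam_table.tsv"), "w", encoding="utf-8") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in meta.items()))
            disc.sam.table.to_csv(fh, sep="\t", index_label="gene", lineterminator="\n")
        _write_json(
            {
                "n_selected": len(sig),
                "achieved_fdr": disc.sam.achieved_fdr,
                "s0": disc.sam.s0,
                "parous_accuracy": disc.parous_accuracy,
                "nulliparous_accuracy": disc.nulliparous_accuracy,
            },
            os.path.join(cfg.out_dir, "discovery.json"),
            meta,
        )
        results["discovery"] = disc

    results["signature"] = sig
    if cfg.test_expression is not None:
        cfg._require_files("test_expression", "test_annotation")
        test = psio.read_expression(cfg.test_expression)
        test_ann = psio.read_annotation(cfg.test_annotation)
        analyses = run_transfer(test, test_ann, sig, cfg)
        summary = transfer_summary(analyses, cfg.fwer_threshold)
        with open(os.path.join(cfg.out_dir, "transfer_summary.tsv"), "w", encoding="utf-8") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in meta.items()))
            summary.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        _write_json(
            {
                "analyses": [
                    {
                        "tissue": a.tissue,
                        "stratum": a.stratum,
                        "skipped": a.skipped_reason,
                        "enrichment": a.enrichment.to_dict() if a.enrichment else None,
                        "association": a.association.to_dict() if a.association else None,
                    }
                    for a in analyses
                ]
            },
            os.path.join(cfg.out_dir, "transfer.json"),
            meta,
        )
        results["transfer"] = analyses
        results["transfer_summary"] = summary
    return results


def simulate_to_dir(cfg: SyntheticConfig, out_dir: str) -> dict[str, str]:
    """Generate a full synthetic study and write it as pipeline-ready TSVs."""
    os.makedirs(out_dir, exist_ok=True)
    meta = {"seed": cfg.seed}
    train, train_ann, truth = simulate_training_cohort(cfg)
    test, test_ann = simulate_test_cohort(cfg, truth)
    paths = {
        "training_expression": os.path.join(out_dir, "training_expression.tsv"),
        "training_annotation": os.path.join(out_dir, "training_annotation.tsv"),
        "test_expression": os.path.join(out_dir, "test_expression.tsv"),
        "test_annotation": os.path.join(out_dir, "test_annotation.tsv"),
        "truth_signature": os.path.join(out_dir, "truth_signature.tsv"),
    }
    psio.write_expression(train, paths["training_expression"], meta)
    psio.write_annotation(train_ann, paths["training_annotation"], meta)
    psio.write_expression(test, paths["test_expression"], meta)
    psio.write_annotation(test_ann, paths["test_annotation"], meta)
    psio.write_signature(truth, paths["truth_signature"], metadata=meta)
    cfg.to_yaml(os.path.join(out_dir, "synthetic_config.yaml"))
    return paths
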