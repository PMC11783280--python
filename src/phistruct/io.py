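"""Shared format readers/writers and the end-to-end pipeline.

All intermediates are plain-text files with documented schemas:

* protein table TSV: id, phage_id, product, sequence, host_genus
* embedding TSV: id, label, e0..e{L-1}
* cluster TSV: id, cluster_id, is_representative (plus a .clstr-style text)
* split TSV: id, split in {train, test}, is_outgroup
* metric report TSV: one row per confidence threshold k
* JSON summary stamped with the config hash and seed

`run_pipeline` chains the stages in order — simulate, catalog, tokenize,
embed, split, balance, train, evaluate — writing every artifact under one
output directory.  Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import evalkit
from .balance import SmoteTomek, TomekPolicy
from .classifier import StructEmbeddingMLP
from .embed import EmbeddedDataset, OUTGROUP_LABEL, SyntheticEmbedder, write_embeddings
from .errors import ConfigError, FormatError
from .rbp_catalog import (
    AnnotationDecision,
    AnnotationRuleSet,
    ProteinRecord,
    classify_annotation,
    deduplicate,
    filter_length_outliers,
    load_default_rules,
)
from .simsplit import SplitPlan, build_split, greedy_cluster
from .structok import MaskKind, MaskStrategy, apply_mask
from .synthetic_data import (
    ESKAPEE_GENERA,
    GeneratorConfig,
    generate_full_dataset,
)

__all__ = [
    "PipelineConfig",
    "read_fasta",
    "read_protein_tsv",
    "run_pipeline",
    "write_clusters",
    "write_fasta",
    "write_protein_tsv",
    "write_split",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- formats


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Read FASTA as (id, description, sequence) triples.

    Lowercase sequence letters are uppercased with a logged warning.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if seq != seq.upper():
            logger.warning("record %s: lowercase sequence uppercased", rec.id)
            seq = seq.upper()
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append((rec.id, desc, seq))
    return out


def write_fasta(records, path) -> None:
    """Write (id, description, sequence) triples, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(seq), id=rid, description=desc)
        for rid, desc, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_PROTEIN_COLUMNS = ["id", "phage_id", "product", "sequence", "host_genus"]


def write_protein_tsv(records: list[ProteinRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id,
                "phage_id": r.phage_id,
                "product": r.product,
                "sequence": r.sequence,
                "host_genus": r.host_genus if r.host_genus is not None else "",
            }
            for r in records
        ],
        columns=_PROTEIN_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_protein_tsv(path) -> list[ProteinRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _PROTEIN_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        ProteinRecord(
            id=row.id,
            phage_id=row.phage_id,
            product=row.product,
            sequence=row.sequence,
            host_genus=row.host_genus or None,
        )
        for row in df.itertuples()
    ]


def write_clusters(clusters, path_tsv, path_clstr=None) -> None:
    rows = []
    lines = []
    for idx, cluster in enumerate(clusters):
        lines.append(f">Cluster {idx}")
        for m, member in enumerate(cluster.member_ids):
            flag = "*" if member == cluster.representative_id else ""
            lines.append(f"{m}\t>{member}... {flag}")
            rows.append(
                {
                    "id": member,
                    "cluster_id": idx,
                    "is_representative": member == cluster.representative_id,
                }
            )
    pd.DataFrame(rows).to_csv(path_tsv, sep="\t", index=False)
    if path_clstr is not None:
        Path(path_clstr).write_text("\n".join(lines) + "\n")


def write_split(plan: SplitPlan, path) -> None:
    outgroup = set(plan.outgroup_ids)
    rows = [
        {"id": i, "split": "train", "is_outgroup": False} for i in plan.train_ids
    ] + [
        {"id": i, "split": "test", "is_outgroup": i in outgroup}
        for i in plan.test_ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- pipeline


_MASK_KINDS = {k.value: k for k in MaskKind}


@dataclass
class PipelineConfig:
    """Top-level configuration of the end-to-end run.

    Parsed from YAML with strict key checking: unknown keys anywhere are a
    configuration error naming their location.
    """

    seed: int = 0
    s: float = 0.4
    train_fraction: float = 0.7
    mask: str = "none"
    plddt_threshold: float = 70.0
    k_grid: list[float] = field(default_factory=lambda: list(evalkit.DEFAULT_K_GRID))
    epochs: int = 200
    batch_size: int = 128
    learning_rate: float = 1e-3
    l2_strength: float = 1e-4
    dropout_rate: float = 0.2
    smote_k_neighbors: int = 5
    tomek_policy: str = "both"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self) -> None:
        if not (0.0 < self.s <= 1.0):
            raise ConfigError(f"s must be in (0, 1], got {self.s}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigError(
                f"train_fraction must be in (0, 1), got {self.train_fraction}"
            )
        if self.mask not in _MASK_KINDS:
            raise ConfigError(
                f"mask must be one of {sorted(_MASK_KINDS)}, got {self.mask!r}"
            )
        if self.tomek_policy not in ("both", "majority"):
            raise ConfigError(f"tomek_policy must be 'both' or 'majority'")
        if any(k < 0 or k > 1 for k in self.k_grid):
            raise ConfigError("k_grid values must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
        gen_raw = raw.pop("generator", {})
        if not isinstance(gen_raw, dict):
            raise ConfigError(f"{path}: 'generator' must be a mapping")
        gen_known = set(GeneratorConfig.__dataclass_fields__)
        gen_unknown = set(gen_raw) - gen_known
        if gen_unknown:
            raise ConfigError(
                f"{path}: unknown keys under 'generator': {sorted(gen_unknown)}"
            )
        return cls(generator=GeneratorConfig(**gen_raw), **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def run_pipeline(config: PipelineConfig, outdir, rules: AnnotationRuleSet | None = None) -> dict:
    """Execute all stages in order; artifacts land under ``outdir``.

    Returns the JSON-ready summary (also written to summary.json). The
    generator's seed and the training seed both derive from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    rules = rules or load_default_rules()

    # stage 1-2: simulate + catalog
    gen = GeneratorConfig(**{**asdict(config.generator), "seed": config.seed})
    logger.info("stage simulate: seed=%d hash=%s", config.seed, stamp["config_hash"])
    bundle = generate_full_dataset(gen)
    write_protein_tsv(bundle.records, outdir / "proteins.tsv")

    audit_rows = []
    rbps = []
    for rec in bundle.records:
        decision = classify_annotation(rec.product, rules)
        audit_rows.append({"id": rec.id, "decision": decision.value, "reason": rec.product})
        if decision is AnnotationDecision.RBP:
            rbps.append(rec)
    kept, removed, stats = filter_length_outliers(rbps)
    for rec in removed:
        audit_rows.append(
            {"id": rec.id, "decision": "LENGTH_OUTLIER",
             "reason": f"length {len(rec)} outside [{stats.lower:.1f}, {stats.upper:.1f}]"}
        )
    rbps = deduplicate(kept)
    pd.DataFrame(audit_rows).to_csv(outdir / "catalog_audit.tsv", sep="\t", index=False)
    write_protein_tsv(rbps, outdir / "rbps.tsv")
    logger.info("stage catalog: %d RBPs kept", len(rbps))

    # stage 3-4: tokenize + embed
    strategy = MaskStrategy(_MASK_KINDS[config.mask], config.plddt_threshold)
    masked = {
        rec.id: apply_mask(bundle.structures.sequences[rec.id], strategy)
        for rec in rbps
    }
    embedder = SyntheticEmbedder(
        classes=list(ESKAPEE_GENERA) + [OUTGROUP_LABEL],
        dim=gen.embed_dim,
        center_separation=gen.center_separation,
        sigma=gen.sigma,
        mask_sensitivity=gen.mask_sensitivity,
        seed=config.seed,
    ).fit()
    dataset = embedder.transform(
        [(rec.id, masked[rec.id], rec.host_genus) for rec in rbps]
    )
    write_embeddings(dataset, outdir / "embeddings.tsv")
    logger.info("stage embed: %d x %d", len(dataset), dataset.dim)

    # stage 5: split (cluster the in-scope records; outgroup is the test-time pool)
    in_scope = [r for r in rbps if r.host_genus != OUTGROUP_LABEL]
    outgroup_pool = [r.id for r in rbps if r.host_genus == OUTGROUP_LABEL]
    clusters = greedy_cluster(in_scope, config.s)
    write_clusters(clusters, outdir / "clusters.tsv", outdir / "clusters.clstr")
    labels = {r.id: r.host_genus for r in rbps}
    plan = build_split(
        clusters, labels, config.s,
        train_fraction=config.train_fraction,
        outgroup_pool=outgroup_pool,
        seed=config.seed,
    )
    write_split(plan, outdir / "split.tsv")

    # stage 6: balance the training side only
    train_set = dataset.subset(plan.train_ids)
    test_set = dataset.subset(plan.test_ids)
    train_labels = np.array(train_set.labels)
    classes_, counts_ = np.unique(train_labels, return_counts=True)
    majority = int(counts_.max())
    target = {}
    for cls, count in zip(classes_.tolist(), counts_.tolist()):
        if count < 2 and count < majority:
            logger.warning(
                "class %r has a single training sample; left unaugmented", cls
            )
            target[cls] = count
        else:
            target[cls] = majority
    balanced = SmoteTomek(
        k_neighbors=config.smote_k_neighbors,
        policy=TomekPolicy(config.tomek_policy),
        seed=config.seed,
        target=target,
    ).fit_resample(train_set.matrix, train_labels)
    logger.info(
        "stage balance: %d -> %d rows (%d synthetic, %d removed)",
        len(train_set), len(balanced.y),
        int(balanced.synthetic_flags.sum()), len(balanced.removed_indices),
    )

    # stage 7: train
    model = StructEmbeddingMLP(
        l2_strength=config.l2_strength,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        dropout_rate=config.dropout_rate,
        random_state=config.seed,
    )
    model.fit(balanced.X, balanced.y)
    model.save(outdir / "model.json")

    # stage 8: evaluate on the untouched test side (outgroup included)
    probs = model.predict_proba(test_set.matrix)
    report = evalkit.pr_curve(
        probs, test_set.labels, k_grid=config.k_grid,
        classes=model.classes_, s=config.s,
    )
    report.insert(0, "config_hash", stamp["config_hash"])
    report.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format="%.10g")
    decisions0 = [evalkit.decide(p, config.k_grid[0], model.classes_) for p in probs]
    evalkit.confusion_matrix(
        test_set.labels, decisions0, model.classes_, normalize="true"
    ).to_csv(outdir / "confusion_k0_truenorm.tsv", sep="\t", float_format="%.10g")

    summary = {
        **stamp,
        "n_records": len(bundle.records),
        "n_rbps": len(rbps),
        "n_train": len(plan.train_ids),
        "n_test": len(plan.test_ids),
        "n_outgroup": len(plan.outgroup_ids),
        "n_train_balanced": int(len(balanced.y)),
        "s": config.s,
        "macro_f1_at_k0": float(report["macro_f1"].iloc[0]),
        "weighted_f1_at_k0": float(report["weighted_f1"].iloc[0]),
        "final_train_loss": model.loss_history_[-1] if model.loss_history_ else None,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
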