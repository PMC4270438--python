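"""Orchestration of the two end-to-end analyses.

``run_transplant_analysis`` composes the limiting-dilution workflow:
per-genotype single-hit frequency estimates, pairwise frequency ratios, and
RU/CRU/MAS tables where donor/host counts are available.

``run_regulome_analysis`` composes the regulome/expression integration:
TF signatures from peaks + TSS annotation, transition fold changes,
trajectory profile of a responsive gene set, the candidate intersection
filter, optional GSEA over signatures and the regulator→target network.

Every run writes a manifest (config hash, seeds, input checksums) so outputs
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from prelsc import expression, lda, network, regulome, setscan
from prelsc.errors import InputError

__all__ = ["RunConfig", "run_transplant_analysis", "run_regulome_analysis"]

DEFAULT_THRESHOLDS = {
    "positivity_pct": 1.0,
    "fold": 1.3,
    "pfp": 0.01,
    "adjusted_p": 0.05,
    "window": 2000,
}

_KNOWN_KEYS = {
    "records",
    "matrix",
    "stages",
    "peaks",
    "tss",
    "tss_format",
    "responsive_set",
    "resources",
    "ranking",
    "upregulated",
    "transition",
    "exclusion_stage",
    "exclusion_fraction",
    "merge",
    "level",
    "seed",
    "out_dir",
    "thresholds",
    "n_perm",
}


@dataclass
class RunConfig:
    """Declarative run configuration; unknown keys are rejected."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.raw) - _KNOWN_KEYS
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        thr = dict(DEFAULT_THRESHOLDS)
        thr.update(self.raw.get("thresholds", {}))
        bad = set(thr) - set(DEFAULT_THRESHOLDS)
        if bad:
            raise InputError(f"unknown threshold keys: {sorted(bad)}")
        self.thresholds = thr

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw=raw)

    def __getitem__(self, key):
        return self.raw[key]

    def get(self, key, default=None):
        return self.raw.get(key, default)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, cfg: RunConfig, inputs: list[Path]) -> None:
    manifest = {
        "config_hash": hashlib.sha256(
            json.dumps(cfg.raw, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "thresholds": cfg.thresholds,
        "seed": cfg.get("seed"),
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_transplant_analysis(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Per-genotype frequencies, pairwise ratios and RU/MAS tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records_path = Path(cfg["records"])
    records = lda.read_transplant_records(records_path)
    level = float(cfg.get("level", 0.95))
    threshold = cfg.thresholds["positivity_pct"]

    cohorts = lda.cohorts_from_records(records, threshold_pct=threshold)
    estimates = {g: lda.fit_single_hit(c, level=level) for g, c in cohorts.items()}
    freq_rows = []
    for g in sorted(estimates):
        e = estimates[g]
        freq_rows.append(
            {
                "genotype": g,
                "f_hat": e.f_hat,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "level": e.level,
                "boundary": e.boundary or "",
                "one_per": (1.0 / e.f_hat) if e.f_hat > 0 else float("inf"),
            }
        )
    freq_df = pd.DataFrame(freq_rows)
    freq_df.to_csv(out_dir / "frequencies.tsv", sep="\t", index=False)

    ratio_rows = [
        {
            "genotype_a": ga,
            "genotype_b": gb,
            "ratio": r.ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "level": r.level,
        }
        for ga, gb, r in lda.pairwise_ratios(estimates)
    ]
    ratio_df = pd.DataFrame(
        ratio_rows,
        columns=["genotype_a", "genotype_b", "ratio", "ci_low", "ci_high", "level"],
    )
    ratio_df.to_csv(out_dir / "ratios.tsv", sep="\t", index=False)

    # RU per mouse where absolute donor/host counts were recorded
    ru_rows = []
    with_counts = records.dropna(subset=["donor_cells", "host_cells"])
    for _, row in with_counts.iterrows():
        ru_rows.append(
            {
                "mouse_id": row["mouse_id"],
                "genotype": row["genotype"],
                "RU": lda.compute_RU(row["donor_cells"], row["host_cells"]),
            }
        )
    ru_df = pd.DataFrame(ru_rows, columns=["mouse_id", "genotype", "RU"])
    ru_df.to_csv(out_dir / "repopulating_units.tsv", sep="\t", index=False)

    _write_manifest(out_dir, cfg, [records_path])
    return {"frequencies": freq_df, "ratios": ratio_df, "RU": ru_df}


def run_regulome_analysis(cfg: RunConfig, out_dir: str | Path) -> dict:
    """TF signatures → trajectory profile → candidate filter → network."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs: list[Path] = []

    stages = tuple(cfg.get("stages") or expression.DEFAULT_STAGES)
    matrix_path = Path(cfg["matrix"])
    inputs.append(matrix_path)
    matrix = expression.read_stage_matrix(matrix_path, stages)

    tss_path = Path(cfg["tss"])
    inputs.append(tss_path)
    tss = regulome.read_tss(tss_path, fmt=cfg.get("tss_format", "bed"))

    window = int(cfg.thresholds["window"])
    merge = cfg.get("merge", "union")
    peak_paths = [Path(p) for p in cfg["peaks"]]
    inputs.extend(peak_paths)
    peaksets = [regulome.read_bed(p) for p in peak_paths]
    by_reg: dict[str, list[regulome.PeakSet]] = {}
    for ps in peaksets:
        by_reg.setdefault(ps.regulator, []).append(ps)
    signatures = [
        regulome.build_signature(group, tss, window=window, merge=merge)
        for group in by_reg.values()
    ]
    regulome.write_gmt(signatures, out_dir / "tf_signatures.gmt")

    # identifier-space sanity: peaks annotation vs expression matrix
    ann_genes = tss.genes
    expr_genes = set(matrix.genes)
    overlap = ann_genes & expr_genes
    if not overlap:
        raise InputError(
            "no gene identifiers shared between TSS annotation "
            f"({len(ann_genes)}) and expression matrix ({len(expr_genes)})"
        )

    fc = expression.transition_fold_changes(matrix)
    fold = float(cfg.thresholds["fold"])

    responsive_sets = setscan.read_gmt(Path(cfg["responsive_set"]))
    inputs.append(Path(cfg["responsive_set"]))
    responsive = responsive_sets[0]

    profile = setscan.trajectory_profile(responsive, fc, threshold=fold)
    profile.to_frame().to_csv(out_dir / "trajectory_profile.tsv", sep="\t")

    resources: list[setscan.GeneSet] = []
    for rp in cfg.get("resources", []):
        inputs.append(Path(rp))
        resources.extend(setscan.read_gmt(rp))

    transition = cfg.get("transition") or fc.transitions[1]
    exclusion = None
    if cfg.get("exclusion_stage"):
        exclusion = setscan.StageExclusionRule(
            stage=cfg["exclusion_stage"],
            fraction_of_max=float(cfg.get("exclusion_fraction", 0.8)),
        )
    bound = signatures[0]
    report = setscan.candidate_filter(
        bound,
        responsive,
        fc,
        transition=transition,
        resources=resources,
        threshold=fold,
        exclusion=exclusion,
        expression=matrix,
    )
    report.to_frame().to_csv(out_dir / "filter_report.tsv", sep="\t", index=False)
    with open(out_dir / "filter_report.json", "w") as fh:
        json.dump(
            [
                {
                    "step": s.name,
                    "n_input": s.n_input,
                    "n_output": s.n_output,
                    "survivors": sorted(s.survivors),
                }
                for s in report.steps
            ],
            fh,
            indent=2,
        )

    results: dict = {
        "signatures": signatures,
        "profile": profile,
        "filter_report": report,
    }

    if cfg.get("ranking"):
        ranking_path = Path(cfg["ranking"])
        inputs.append(ranking_path)
        ranking = pd.read_csv(
            ranking_path, sep="\t", index_col=0, header=None, names=["gene", "score"]
        )["score"]
        sets = [
            setscan.GeneSet(sig.regulator, sig.genes)
            for sig in signatures
            if sig.genes & set(ranking.index)
        ]
        if sets:
            enr = setscan.gsea_collection(
                ranking,
                sets,
                n_perm=int(cfg.get("n_perm", 1000)),
                seed=cfg.get("seed"),
            )
            enr.to_csv(out_dir / "gsea.tsv", sep="\t")
            results["gsea"] = enr

    if cfg.get("upregulated"):
        up_path = Path(cfg["upregulated"])
        inputs.append(up_path)
        upregulated = setscan.read_gmt(up_path)[0]
        net = network.build_network(signatures, upregulated)
        network.write_network(net, out_dir / "edges.tsv", out_dir / "nodes.tsv")
        results["network"] = net

    _write_manifest(out_dir, cfg, inputs)
    return results
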