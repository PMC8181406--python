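"""End-to-end pipeline driver: one config in, a report bundle out.

Wires the stages together for a scripted run: SASA/interface analysis of a
complex, hydrogen-bond detection, per-mutation feature extraction, rule-based
structural-basis classification, group statistics, and (optionally) SVM
training.  Every threshold used is echoed into the report for provenance, and
all outputs are deterministic for a fixed config and seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import basis as basis_mod
from . import features as feat_mod
from . import interface as iface_mod
from . import stats as stats_mod
from . import svm as svm_mod
from .curation import MutationRecord, load_mutation_table
from .structures import extract_chain, read_structure
from .surface import relative_sasa, shrake_rupley

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


_KNOWN_KEYS = {
    "structure", "subject_chain", "partner_chains", "mutations", "ddg_table",
    "conservation", "out_dir", "seed", "d_max", "angle_min", "bsa_threshold",
    "buried_threshold", "steric_threshold", "ddg_cutoff", "rmsf_threshold",
    "n_sphere_points", "train", "candidate_features", "min_features",
    "helix_intervals",
}


@dataclass
class RunConfig:
    structure: str
    subject_chain: str
    partner_chains: list[str]
    mutations: str                       # mutation TSV path
    out_dir: str
    ddg_table: str | None = None
    conservation: str | None = None      # TSV: position <tab> score
    seed: int = 0
    d_max: float = 3.5
    angle_min: float = 120.0
    bsa_threshold: float = 0.1
    buried_threshold: float = 0.2
    steric_threshold: float = 30.0
    ddg_cutoff: float = 1.0
    rmsf_threshold: float = 2.0
    n_sphere_points: int = 960
    train: bool = False
    candidate_features: list[str] = field(default_factory=lambda: list(
        feat_mod.CORE_FEATURES))
    min_features: int = 5
    helix_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("d_max", "angle_min", "bsa_threshold", "buried_threshold",
                     "steric_threshold", "ddg_cutoff", "rmsf_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _load_conservation(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return {int(p): float(s) for p, s in zip(df[cols[0]], df[cols[1]])}


def _in_any(position: int, intervals) -> bool:
    return any(lo <= position <= hi for lo, hi in intervals)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; write per-stage TSV/JSON under ``config.out_dir``.

    Returns the combined report dictionary (also written as report.json).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"thresholds": {
        k: getattr(config, k) for k in
        ("d_max", "angle_min", "bsa_threshold", "buried_threshold",
         "steric_threshold", "ddg_cutoff", "rmsf_threshold",
         "n_sphere_points", "seed")
    }}

    try:
        model = read_structure(config.structure)
        if hasattr(model, "models"):
            model = model.models[0]
    except Exception as exc:
        raise PipelineError("read_structure", str(exc)) from exc

    try:
        subject = config.subject_chain
        records = iface_mod.interface_residues(
            model, subject, config.partner_chains,
            bsa_threshold=config.bsa_threshold,
            n_points=config.n_sphere_points)
        bonds = iface_mod.hydrogen_bonds(
            model, [subject], config.partner_chains,
            d_max=config.d_max, angle_min=config.angle_min)
        hb_counts = iface_mod.hbonds_per_residue(bonds, subject)
        alone = shrake_rupley(extract_chain(model, subject),
                              n_points=config.n_sphere_points)
        rsasa = {}
        for res in model.residues(subject):
            if res.kind == "protein":
                rsasa[res.number] = relative_sasa(alone.per_residue[res.key],
                                                  res.name)
        chain_len = sum(1 for _ in model.residues(subject))
        iface_df = pd.DataFrame([dataclasses.asdict(r) for r in records])
        iface_df.to_csv(out / "interface.tsv", sep="\t", index=False,
                        float_format="%.4f")
        pd.DataFrame([dataclasses.asdict(b) for b in bonds]).to_csv(
            out / "hbonds.tsv", sep="\t", index=False, float_format="%.3f")
        report["interface"] = {
            "n_interface_residues": int(sum(r.is_interface for r in records)),
            "interface_fraction_pct": iface_mod.interface_fraction(records, chain_len),
            "n_hydrogen_bonds": len(bonds),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("interface", str(exc)) from exc

    try:
        mutations = load_mutation_table(config.mutations)
        ddg = (feat_mod.load_ddg_table(config.ddg_table)
               if config.ddg_table else None)
        cons = (_load_conservation(config.conservation)
                if config.conservation else None)
        by_number = {r.residue_number: r for r in records}
        rows, bases = [], []
        for m in mutations:
            fv = feat_mod.extract_features(m, records, hb_counts, rsasa,
                                           ddg=ddg, conservation=cons)
            rec = by_number.get(m.position)
            roles = set()
            for b in bonds:
                for chain, num, atom in ((b.donor_chain, b.donor_residue, "donor"),
                                         (b.acceptor_chain, b.acceptor_residue,
                                          "acceptor")):
                    if chain == subject and num == m.position:
                        roles.add(atom)
            ctx = basis_mod.MutationContext(
                rsasa=rsasa.get(m.position, 0.0),
                in_helix=_in_any(m.position, config.helix_intervals),
                is_interface=bool(rec and rec.is_interface),
                wt_hbond_roles=frozenset(roles),
            )
            rule_cfg = basis_mod.RuleConfig(
                ddg_cutoff=config.ddg_cutoff,
                buried_threshold=config.buried_threshold,
                steric_threshold=config.steric_threshold)
            sb = basis_mod.classify_mutation(m, fv, ctx, rule_cfg)
            bases.append(sb)
            row = {"mutation": m.name, "label": m.label}
            row.update(feat_mod.features_to_row(fv))
            row.update({
                "destabilizing": sb.destabilizing,
                "approaches": "|".join(sorted(sb.approaches)),
                "interaction_disrupting": sb.interaction_disrupting,
                "avenues": "|".join(sorted(sb.avenues)),
                "patch": sb.patch or "",
                "notes": sb.notes,
            })
            rows.append(row)
        feat_df = pd.DataFrame(rows)
        feat_df.to_csv(out / "features.tsv", sep="\t", index=False,
                       float_format="%.4f")
        report["basis"] = basis_mod.summarize_basis(bases)
        report["ddg_available"] = ddg is not None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    try:
        stats_report = {}
        for column in ("ddg", "rsasa", "conservation"):
            if column not in feat_df.columns:
                continue
            sub = feat_df[["label", column]].dropna()
            pos = sub.loc[sub["label"] == "dba", column]
            neg = sub.loc[sub["label"] == "neutral", column]
            if len(pos) and len(neg):
                alt = "greater" if column == "ddg" else "less"
                cmp_res = stats_mod.mann_whitney_one_tailed(pos, neg, alt)
                stats_report[column] = dataclasses.asdict(cmp_res)
        report["group_stats"] = stats_report
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    if config.train:
        try:
            train_df = feat_df[feat_df["label"].isin(["dba", "neutral"])].copy()
            cfg = svm_mod.TrainingConfig(
                candidate_features=tuple(config.candidate_features),
                min_features=config.min_features, seed=config.seed)
            feats, c, gamma, mcc = svm_mod.select_features_and_hyperparams(
                train_df, cfg)
            model_fit = svm_mod.train_final(train_df, feats, c, gamma,
                                            cv_mcc=mcc, seed=config.seed)
            model_fit.save(out / "model.json")
            report["svm"] = {"selected_features": list(feats), "c": c,
                             "gamma": gamma, "cv_mcc": mcc}
        except Exception as exc:
            raise PipelineError("train", str(exc)) from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
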