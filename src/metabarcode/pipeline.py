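"""End-to-end orchestration: tally -> barcode -> network -> RWR -> predict -> synergy.

Every stage is a pure function of (inputs, parameters, seeds); the run
directory collects each stage's tables plus a JSON manifest recording
parameters, seeds, and input hashes, so a rerun with the same config is
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .library import (
    filter_by_frequency,
    load_alias_map,
    load_library,
    normalize_ids,
    tally_votes,
    votes_to_frame,
)
from .network import assemble_network, featurize_combinations, load_edges
from .prediction import (
    ClassifierSpec,
    CombinationRecord,
    encode_labels,
    rank_sensitizers,
    split_train_test,
    holdout_accuracy,
    tune_and_fit,
)
from .synergy import synergy_table
from .votecount import barcode_to_frame, build_barcode, compare_methods

logger = logging.getLogger(__name__)

STAGES = ("tally", "barcode", "network", "rwr", "predict", "synergy")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    library: str
    stitch_edges: str
    string_edges: str
    drug_targets: str
    combos: str
    plate: str
    out_dir: str
    alias_map: str | None = None
    backbone_drug: str | None = None
    min_frequency: int = 3
    bf_threshold: float = 3.0
    lam: float = 0.5
    score_threshold: float = 0.0
    split_fraction: float = 0.8
    cv_folds: int = 10
    q_threshold: float = 1.15
    alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for name in ("library", "stitch_edges", "string_edges", "drug_targets", "combos", "plate"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config.{name}: {p} does not exist")
        if not 0 < self.lam <= 1:
            raise ValueError("lambda must lie in (0, 1]")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split fraction must lie in (0, 1)")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def load_drug_targets(path) -> dict[str, list[str]]:
    """Read the two-column drug_id / target_id TSV into a dict of lists."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"drug_id", "target_id"}.issubset(frame.columns):
        raise ValueError("drug-target map needs columns: drug_id, target_id")
    return {
        drug: sorted(g["target_id"]) for drug, g in frame.groupby("drug_id")
    }


def load_combinations(path) -> list[CombinationRecord]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"drug_a", "drug_b", "cell_line", "label"}
    if not needed.issubset(frame.columns):
        raise ValueError(f"combination table needs columns {sorted(needed)}")
    return [
        CombinationRecord(r.drug_a, r.drug_b, r.cell_line, r.label)
        for r in frame.itertuples(index=False)
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all six stages, returning (and writing) the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("out_dir",)
        },
        "inputs": {
            name: _sha256(getattr(config, name))
            for name in (
                "library",
                "stitch_edges",
                "string_edges",
                "drug_targets",
                "combos",
                "plate",
            )
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            logger.info("stage %s", name)
            try:
                manifest["stages"][name] = fn()
            except Exception as exc:
                (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return fn

        return deco

    state: dict = {}

    @stage("tally")
    def _tally():
        records = load_library(config.library)
        if config.alias_map:
            records = normalize_ids(records, load_alias_map(config.alias_map))
        records = [r for r in records if r.sample_type != "feces"]
        state["votes"] = {}
        info = {"n_studies": len(records)}
        for st in ("blood", "tissue"):
            votes = tally_votes(records, st)
            kept = filter_by_frequency(votes, config.min_frequency)
            state["votes"][st] = kept
            votes_to_frame(votes).to_csv(out / f"votes_{st}.tsv", sep="\t", index=False)
            info[f"n_metabolites_{st}"] = len(votes)
            info[f"n_frequent_{st}"] = len(kept)
        return info

    @stage("barcode")
    def _barcode():
        info = {}
        state["barcodes"] = {}
        for st in ("blood", "tissue"):
            entries = build_barcode(
                state["votes"][st],
                bf_threshold=config.bf_threshold,
                min_frequency=config.min_frequency,
            )
            state["barcodes"][st] = entries
            barcode_to_frame(entries).to_csv(out / f"barcode_{st}.tsv", sep="\t", index=False)
            comparison = compare_methods(
                state["votes"][st], bf_threshold=config.bf_threshold, alpha=config.alpha
            )
            comparison.to_csv(out / f"method_comparison_{st}.tsv", sep="\t", index=False)
            info[f"n_entries_{st}"] = len(entries)
            info[f"detected_bayes_{st}"] = comparison.attrs["n_detected_bayes"]
            info[f"detected_sign_{st}"] = comparison.attrs["n_detected_sign"]
        return info

    @stage("network")
    def _network():
        met_ids = [e.metabolite_id for e in state["barcodes"]["tissue"]]
        met_prot = load_edges(config.stitch_edges, config.score_threshold)
        prot_prot = load_edges(config.string_edges, config.score_threshold)
        net = assemble_network(met_ids, met_prot, prot_prot)
        state["net"] = net
        pd.DataFrame({"node": net.node_ids, "kind": net.node_kind}).to_csv(
            out / "nodes.tsv", sep="\t", index=False
        )
        return {"n_nodes": net.N, "n_edges": net.n_edges}

    @stage("rwr")
    def _rwr():
        combos = load_combinations(config.combos)
        state["combos"] = combos
        targets = load_drug_targets(config.drug_targets)
        state["targets"] = targets
        X = featurize_combinations(combos, targets, state["net"], lam=config.lam)
        state["X"] = X
        X.to_csv(out / "predictor_matrix.tsv", sep="\t", index_label="pair_id")
        sidecar = {
            "lambda": config.lam,
            "node_order": state["net"].node_ids,
            "network_sha256": hashlib.sha256(
                state["net"].A.tobytes()
            ).hexdigest(),
        }
        (out / "predictor_matrix.json").write_text(json.dumps(sidecar, indent=2))
        return {"shape": list(X.shape)}

    @stage("predict")
    def _predict():
        combos = state["combos"]
        X = state["X"].loc[[c.pair_id for c in combos]]
        y = encode_labels([c.label for c in combos])
        X_tr, X_te, y_tr, y_te = split_train_test(
            X, y, fraction=config.split_fraction, seed=config.seed
        )
        info = {"n_train": len(X_tr), "n_test": len(X_te)}
        fits = {}
        for family in ("bagged-trees", "boosted-trees"):
            spec = ClassifierSpec(family=family, cv_folds=config.cv_folds, seed=config.seed)
            fit = tune_and_fit(X_tr, y_tr, spec)
            fits[family] = fit
            fit.cv_table.to_csv(out / f"cv_{family}.tsv", sep="\t", index=False)
            info[family] = {
                "best_params": fit.best_params,
                "cv_error": fit.cv_error,
                "test_accuracy": holdout_accuracy(fit, X_te, y_te),
            }
        if config.backbone_drug:
            candidates = sorted(
                d for d in state["targets"] if d != config.backbone_drug
            )
            ranking = rank_sensitizers(
                fits,
                config.backbone_drug,
                candidates,
                state["targets"],
                state["net"],
                lam=config.lam,
            )
            ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
            info["n_ranked"] = len(ranking)
        return info

    @stage("synergy")
    def _synergy():
        plate = pd.read_csv(config.plate)
        table = synergy_table(
            plate, q_threshold=config.q_threshold, alpha=config.alpha
        )
        table.to_csv(out / "synergy_table.tsv", sep="\t", index=False)
        return {
            "n_dose_pairs": len(table),
            "n_synergistic": int(table["synergistic"].sum()),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
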