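"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its seed and emits a machine-readable
ground-truth table alongside its data, so parameter-recovery assertions can
live in the test suite rather than in the generators.

The default literature plan mirrors the scale of the curated corpus the
pipeline is designed for: 39 clinical studies (19 blood, 20 tissue),
3202 blood subjects (1332 case / 1870 control), 990 tissue subjects
(495 / 495), 330 reported metabolites of which 254 reach overall frequency
>= 3, with 28 up + 6 down passing the barcode rule in tissue and
15 up + 12 down in blood.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import PLATFORMS, StudyRecord
from .network import InteractionEdge, MetProtNetwork, assemble_network, featurize_combinations
from .prediction import CombinationRecord
from .synergy import PLATE_COLUMNS


# --------------------------------------------------------------------------
# literature library
# --------------------------------------------------------------------------

@dataclass
class LibraryPlan:
    """Blueprint for a synthetic literature library.

    ``metabolites`` has one row per (metabolite, sample_type) with either a
    fixed vote pattern (n_up, n_down planted exactly) or a disorder
    probability ``theta`` under which each of the ``k`` contributing
    studies reports the true direction independently with probability θ.
    ``studies`` fixes the per-study subject sizes and platforms.
    """

    metabolites: pd.DataFrame
    studies: pd.DataFrame
    seed: int = 0


def _partition(total: int, parts: int) -> list[int]:
    base, rem = divmod(total, parts)
    return [base + 1 if i < rem else base for i in range(parts)]


def _study_frame(prefix: str, sample_type: str, n: int, case_total: int, control_total: int) -> pd.DataFrame:
    platforms = list(itertools.islice(itertools.cycle(PLATFORMS), n))
    return pd.DataFrame(
        {
            "study_id": [f"{prefix}{i + 1:02d}" for i in range(n)],
            "sample_type": sample_type,
            "platform": platforms,
            "n_case": _partition(case_total, n),
            "n_control": _partition(control_total, n),
        }
    )


def default_library_plan(seed: int = 0) -> LibraryPlan:
    """Corpus-scale plan with planted tallies (see module docstring)."""
    up_sig = itertools.cycle([(3, 0), (4, 0), (5, 0), (6, 0), (7, 0)])
    down_sig = itertools.cycle([(0, 3), (0, 4), (0, 5)])
    non_sig = itertools.cycle([(2, 1), (1, 2), (3, 2), (2, 3), (2, 2)])

    rows: list[dict] = []

    def plant(met: str, sample_type: str, pattern: tuple[int, int]) -> None:
        n_up, n_down = pattern
        rows.append(
            {
                "metabolite_id": met,
                "sample_type": sample_type,
                "true_direction": 1 if n_up >= n_down else -1,
                "theta": np.nan,
                "k": n_up + n_down,
                "n_up": n_up,
                "n_down": n_down,
            }
        )

    mets = [f"M{i:03d}" for i in range(1, 331)]
    # tissue barcode block: 28 up-significant, 6 down, 9 frequent but not significant
    for met in mets[0:28]:
        plant(met, "tissue", next(up_sig))
    for met in mets[28:34]:
        plant(met, "tissue", next(down_sig))
    for met in mets[34:43]:
        plant(met, "tissue", next(non_sig))
    # blood block of 50, sharing 21 ids (M023..M043) with the tissue block
    for met in mets[34:43] + mets[43:49]:  # 15 up-significant
        plant(met, "blood", next(up_sig))
    for met in mets[22:28] + mets[49:55]:  # 12 down-significant
        plant(met, "blood", next(down_sig))
    for met in mets[28:34] + mets[55:72]:  # 23 frequent, not significant
        plant(met, "blood", next(non_sig))
    # 182 metabolites frequent only when both sample types are pooled
    for met in mets[72:254]:
        plant(met, "blood", (1, 1))
        plant(met, "tissue", (1, 0))
    # 76 rarely-reported metabolites (overall frequency <= 2)
    low = itertools.cycle([("blood",), ("tissue",), ("blood", "tissue")])
    for met in mets[254:330]:
        for sample_type in next(low):
            plant(met, sample_type, (1, 0))

    studies = pd.concat(
        [
            _study_frame("B", "blood", 19, 1332, 1870),
            _study_frame("T", "tissue", 20, 495, 495),
        ],
        ignore_index=True,
    )
    return LibraryPlan(metabolites=pd.DataFrame(rows), studies=studies, seed=seed)


def gen_library(plan: LibraryPlan) -> tuple[list[StudyRecord], pd.DataFrame]:
    """Realize a plan into study records plus a ground-truth table.

    Rows with a fixed (n_up, n_down) pattern are dealt exactly; rows with a
    ``theta`` draw each report as the true direction with probability θ
    (flipped otherwise). Contributing studies are sampled without
    replacement within the row's sample type.
    """
    rng = np.random.default_rng(plan.seed)
    records: dict[str, StudyRecord] = {}
    for row in plan.studies.itertuples(index=False):
        records[row.study_id] = StudyRecord(
            study_id=row.study_id,
            sample_type=row.sample_type,
            platform=row.platform,
            n_case=int(row.n_case),
            n_control=int(row.n_control),
        )
    by_type: dict[str, list[str]] = {
        st: list(g["study_id"]) for st, g in plan.studies.groupby("sample_type")
    }

    metabolites = plan.metabolites.copy()
    for col in ("theta", "n_up", "n_down"):
        if col not in metabolites.columns:
            metabolites[col] = np.nan

    truth_rows = []
    for row in metabolites.itertuples(index=False):
        pool = by_type[row.sample_type]
        k = int(row.k)
        if k > len(pool):
            raise ValueError(
                f"{row.metabolite_id}: {k} reports requested but only "
                f"{len(pool)} {row.sample_type} studies exist"
            )
        chosen = rng.choice(pool, size=k, replace=False)
        if not np.isnan(row.n_up):
            directions = [1] * int(row.n_up) + [-1] * int(row.n_down)
            rng.shuffle(directions)
        else:
            flips = rng.random(k) < float(row.theta)
            directions = [int(row.true_direction) if f else -int(row.true_direction) for f in flips]
        for study_id, direction in zip(chosen, directions):
            records[study_id].reports.append((row.metabolite_id, direction))
        truth_rows.append(
            {
                "metabolite_id": row.metabolite_id,
                "sample_type": row.sample_type,
                "true_direction": int(row.true_direction),
                "k": k,
                "n_up": int(np.sum(np.array(directions) == 1)),
                "n_down": int(np.sum(np.array(directions) == -1)),
            }
        )
    # re-validate invariants after mutation
    out = []
    for rec in records.values():
        out.append(
            StudyRecord(
                study_id=rec.study_id,
                sample_type=rec.sample_type,
                platform=rec.platform,
                n_case=rec.n_case,
                n_control=rec.n_control,
                reports=rec.reports,
            )
        )
    return out, pd.DataFrame(truth_rows)


# --------------------------------------------------------------------------
# network
# --------------------------------------------------------------------------

@dataclass
class NetworkPlan:
    """Blueprint for a desk-scale random metabolite-protein network."""

    n_metabolites: int = 10
    n_proteins: int = 110
    mean_degree: float = 4.0
    met_links: int = 3  # proteins attached to each metabolite
    weight_low: float = 0.4
    weight_high: float = 1.0
    seed: int = 0
    max_attempts: int = 50


@dataclass
class GeneratedNetwork:
    net: MetProtNetwork
    metabolite_ids: list[str]
    met_prot_edges: list[InteractionEdge]
    prot_prot_edges: list[InteractionEdge]
    planted_nodes: int
    planted_edges: int


def gen_network(plan: NetworkPlan, out_dir=None) -> GeneratedNetwork:
    """Random bipartite metabolite-protein edges plus a protein-protein
    Erdős–Rényi layer, regenerated until cleanup leaves one connected
    component. Optionally writes STITCH- and STRING-dialect TSVs.
    """
    import networkx as nx

    for attempt in range(plan.max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence([plan.seed, attempt]))
        mets = [f"C{i:05d}" for i in range(1, plan.n_metabolites + 1)]
        prots = [f"P{i:04d}" for i in range(1, plan.n_proteins + 1)]

        def w() -> float:
            return float(rng.uniform(plan.weight_low, plan.weight_high))

        met_prot = []
        for met in mets:
            for prot in rng.choice(prots, size=min(plan.met_links, len(prots)), replace=False):
                met_prot.append(InteractionEdge(met, str(prot), w()))
        p_edge = plan.mean_degree / max(plan.n_proteins - 1, 1)
        prot_prot = []
        for i, a in enumerate(prots):
            for b in prots[i + 1 :]:
                if rng.random() < p_edge:
                    prot_prot.append(InteractionEdge(a, b, w()))
        try:
            net = assemble_network(mets, met_prot, prot_prot)
        except ValueError:
            continue
        graph = nx.from_numpy_array(net.A)
        if not nx.is_connected(graph):
            continue
        if out_dir is not None:
            _write_edge_files(out_dir, met_prot, prot_prot)
        return GeneratedNetwork(
            net=net,
            metabolite_ids=mets,
            met_prot_edges=met_prot,
            prot_prot_edges=prot_prot,
            planted_nodes=net.N,
            planted_edges=net.n_edges,
        )
    raise RuntimeError("could not generate a connected network; relax the plan")


def _write_edge_files(out_dir, met_prot, prot_prot) -> tuple[str, str]:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stitch = out / "stitch_edges.tsv"
    string = out / "string_edges.tsv"
    pd.DataFrame(
        {
            "chemical": [e.node_a for e in met_prot],
            "protein": [e.node_b for e in met_prot],
            "combined_score": [int(round(e.weight * 999)) for e in met_prot],
        }
    ).to_csv(stitch, sep="\t", index=False)
    pd.DataFrame(
        {
            "protein1": [e.node_a for e in prot_prot],
            "protein2": [e.node_b for e in prot_prot],
            "combined_score": [int(round(e.weight * 999)) for e in prot_prot],
        }
    ).to_csv(string, sep="\t", index=False)
    return str(stitch), str(string)


# --------------------------------------------------------------------------
# drug combinations with a planted synergy signal
# --------------------------------------------------------------------------

@dataclass
class SynergyPlan:
    """Blueprint for labeled combinations carrying a recoverable signal.

    Labels follow a hidden sparse linear rule over the RWR feature space
    (score = w · profile, synergistic above the median score), then flip
    with probability ``label_noise``. The hidden weights are positive and
    concentrated on a random "hub" subset of protein nodes, and each drug
    either targets the hub set or its complement; a fraction sqrt(1/2) of
    hub-targeting drugs puts the both-hub pairs just above the median, so
    the induced scores separate cleanly there and the rule is recoverable
    by construction rather than by chance.
    """

    n_drugs: int = 60
    targets_low: int = 2
    targets_high: int = 6
    n_combinations: int = 541
    hub_size: int = 12
    hub_fraction: float = 0.7071  # sqrt(1/2): both-hub pairs ~ half of all pairs
    label_noise: float = 0.1
    lam: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label noise must lie in [0, 0.5)")
        if self.hub_size < self.targets_high:
            raise ValueError("hub must be at least as large as a target set")


@dataclass
class GeneratedCombinations:
    drug_targets: dict[str, list[str]]
    records: list[CombinationRecord]
    features: pd.DataFrame
    truth: pd.DataFrame
    hidden_weights: np.ndarray


def gen_combinations(plan: SynergyPlan, net: MetProtNetwork) -> GeneratedCombinations:
    """Random drugs, random unordered pairs, hidden-rule labels with noise."""
    rng = np.random.default_rng(plan.seed)
    proteins = [n for n, kind in zip(net.node_ids, net.node_kind) if kind == "protein"]
    if len(proteins) < 2 * plan.hub_size:
        raise ValueError("network too small for the planned hub")
    drugs = [f"D{i:03d}" for i in range(1, plan.n_drugs + 1)]

    hub = sorted(rng.choice(proteins, size=plan.hub_size, replace=False))
    non_hub = [p for p in proteins if p not in set(hub)]
    n_hub_drugs = int(round(plan.hub_fraction * plan.n_drugs))
    hub_drugs = set(rng.choice(drugs, size=n_hub_drugs, replace=False))
    drug_targets = {}
    for d in drugs:
        pool = hub if d in hub_drugs else non_hub
        size = int(rng.integers(plan.targets_low, plan.targets_high + 1))
        drug_targets[d] = sorted(rng.choice(pool, size=size, replace=False))

    all_pairs = list(itertools.combinations(drugs, 2))
    if plan.n_combinations > len(all_pairs):
        raise ValueError("more combinations requested than distinct pairs")
    idx = rng.choice(len(all_pairs), size=plan.n_combinations, replace=False)
    pairs = [all_pairs[i] for i in sorted(idx)]

    X = featurize_combinations(pairs, drug_targets, net, lam=plan.lam)
    weights = np.zeros(net.N)
    hub_idx = [net.index_of(p) for p in hub]
    weights[hub_idx] = 0.5 + np.abs(rng.normal(size=len(hub_idx)))
    scores = X.to_numpy() @ weights
    true_label = scores > np.median(scores)
    flips = rng.random(len(pairs)) < plan.label_noise
    observed = np.where(flips, ~true_label, true_label)

    records = [
        CombinationRecord(
            drug_a=a,
            drug_b=b,
            cell_line="LINE-1",
            label="synergistic" if obs else "non-synergistic",
        )
        for (a, b), obs in zip(pairs, observed)
    ]
    truth = pd.DataFrame(
        {
            "pair_id": ["+".join(p) for p in pairs],
            "score": scores,
            "true_label": true_label.astype(int),
            "observed_label": observed.astype(int),
            "flipped": flips,
        }
    )
    return GeneratedCombinations(
        drug_targets=drug_targets,
        records=records,
        features=X,
        truth=truth,
        hidden_weights=weights,
    )


# --------------------------------------------------------------------------
# consistent end-to-end fixtures
# --------------------------------------------------------------------------

def small_library_plan(metabolite_ids: list[str], seed: int = 0) -> LibraryPlan:
    """Desk-scale library whose barcode metabolites are ``metabolite_ids``.

    Every given metabolite is planted unanimously (frequency >= 3) in
    tissue so it enters the tissue barcode; a few extras stay below the
    frequency threshold. Suitable as the library half of a pipeline
    fixture whose network half uses the same metabolite ids.
    """
    patterns = itertools.cycle([(3, 0), (4, 0), (0, 3), (5, 0), (0, 4)])
    rows = []
    for met in metabolite_ids:
        n_up, n_down = next(patterns)
        rows.append(
            {
                "metabolite_id": met,
                "sample_type": "tissue",
                "true_direction": 1 if n_up >= n_down else -1,
                "theta": np.nan,
                "k": n_up + n_down,
                "n_up": n_up,
                "n_down": n_down,
            }
        )
    for met in metabolite_ids[: len(metabolite_ids) // 2]:
        rows.append(
            {
                "metabolite_id": met,
                "sample_type": "blood",
                "true_direction": 1,
                "theta": np.nan,
                "k": 3,
                "n_up": 3,
                "n_down": 0,
            }
        )
    for i in range(3):  # below-threshold extras
        rows.append(
            {
                "metabolite_id": f"X{i:02d}",
                "sample_type": "tissue",
                "true_direction": 1,
                "theta": np.nan,
                "k": 2,
                "n_up": 2,
                "n_down": 0,
            }
        )
    studies = pd.concat(
        [
            _study_frame("B", "blood", 6, 120, 140),
            _study_frame("T", "tissue", 6, 90, 90),
        ],
        ignore_index=True,
    )
    return LibraryPlan(metabolites=pd.DataFrame(rows), studies=studies, seed=seed)


def make_pipeline_fixtures(out_dir, seed: int = 0) -> dict[str, str]:
    """Write one mutually consistent set of pipeline inputs to ``out_dir``.

    Produces library.tsv, stitch_edges.tsv, string_edges.tsv,
    drug_targets.tsv, combos.tsv and plate.csv whose identifiers agree, so
    the full pipeline can run end to end. Returns the path map.
    """
    from pathlib import Path

    from .library import write_library

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gen = gen_network(NetworkPlan(seed=seed), out_dir=out)
    plan = small_library_plan(gen.metabolite_ids, seed=seed)
    records, _ = gen_library(plan)
    write_library(records, out / "library.tsv")

    combo = gen_combinations(
        SynergyPlan(n_drugs=20, n_combinations=80, seed=seed), gen.net
    )
    pd.DataFrame(
        [
            {"drug_id": d, "target_id": t}
            for d, targets in sorted(combo.drug_targets.items())
            for t in targets
        ]
    ).to_csv(out / "drug_targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "drug_a": [r.drug_a for r in combo.records],
            "drug_b": [r.drug_b for r in combo.records],
            "cell_line": [r.cell_line for r in combo.records],
            "label": [r.label for r in combo.records],
        }
    ).to_csv(out / "combos.tsv", sep="\t", index=False)

    plate = gen_plate(
        {"drug_a": 0.6, "drug_b": 0.7, "combination": 0.6 * 0.7 * 0.7},
        n_wells=6,
        noise_sd=0.03,
        seed=seed,
    )
    plate.to_csv(out / "plate.csv", index=False)

    return {
        "library": str(out / "library.tsv"),
        "stitch_edges": str(out / "stitch_edges.tsv"),
        "string_edges": str(out / "string_edges.tsv"),
        "drug_targets": str(out / "drug_targets.tsv"),
        "combos": str(out / "combos.tsv"),
        "plate": str(out / "plate.csv"),
    }


# --------------------------------------------------------------------------
# viability plates
# --------------------------------------------------------------------------

def gen_plate(
    true_survival: dict[str, float],
    n_wells: int = 6,
    noise_sd: float = 0.05,
    seed: int = 0,
    base_od: float = 1.0,
    bliss_null: bool = False,
    control_noise_sd: float | None = None,
    dose_a: float = 10.0,
    dose_b: float = 2.5,
) -> pd.DataFrame:
    """Simulated one-dose-pair MTT plate.

    OD_well = base_od × rate × exp(ε), ε ~ N(0, noise_sd²); the control
    rate is 1. ``bliss_null`` overrides the combination rate with
    rate_a × rate_b (exact Bliss independence on the survival scale).
    ``control_noise_sd`` lets the control wells carry a different noise
    level (0 gives an exactly-known normalizing constant, the regime in
    which the Bliss t-test's null distribution is exact).
    """
    rng = np.random.default_rng(seed)
    rates = dict(true_survival)
    rates.setdefault("control", 1.0)
    if bliss_null:
        rates["combination"] = rates["drug_a"] * rates["drug_b"]
    for group, rate in rates.items():
        if not 0.0 < rate <= 1.0:
            raise ValueError(f"group {group!r}: survival rate must be in (0, 1]")
    if control_noise_sd is None:
        control_noise_sd = noise_sd
    doses = {
        "control": (0.0, 0.0),
        "drug_a": (dose_a, 0.0),
        "drug_b": (0.0, dose_b),
        "combination": (dose_a, dose_b),
    }
    rows = []
    for group in ("control", "drug_a", "drug_b", "combination"):
        sd = control_noise_sd if group == "control" else noise_sd
        eps = rng.normal(0.0, sd, size=n_wells) if sd > 0 else np.zeros(n_wells)
        od = base_od * rates[group] * np.exp(eps)
        for j in range(n_wells):
            rows.append(
                {
                    "group": group,
                    "dose_a_uM": doses[group][0],
                    "dose_b_uM": doses[group][1],
                    "replicate": j + 1,
                    "od490": od[j],
                }
            )
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)


def simulate_plate_rejection_rate(
    n_plates: int = 2000,
    survival_a: float = 0.6,
    survival_b: float = 0.7,
    combo_multiplier: float = 1.0,
    n_wells: int = 6,
    noise_sd: float = 0.05,
    seed: int = 0,
    alpha: float = 0.05,
    require_verdict: bool = False,
) -> float:
    """Fraction of simulated plates rejecting the Bliss null.

    ``combo_multiplier`` = 1 gives exact Bliss independence (the returned
    fraction estimates the type-I error of the two-sided t-test);
    multipliers < 1 plant synergy and the fraction estimates power. With
    ``require_verdict`` the full joint rule (Q >= 1.15, p < alpha, t > 0)
    is applied instead of the p-value alone. Control wells are noiseless
    so the normalizing constant is exactly known — the regime in which the
    t statistic's null distribution is exact (see docs/methods.md).
    """
    from .synergy import bliss_t_test, evaluate_plate, log_survival_groups

    children = np.random.SeedSequence(seed).spawn(n_plates)
    hits = 0
    combo = survival_a * survival_b * combo_multiplier
    for child in children:
        plate = gen_plate(
            {"drug_a": survival_a, "drug_b": survival_b, "combination": combo},
            n_wells=n_wells,
            noise_sd=noise_sd,
            control_noise_sd=0.0,
            seed=child,
        )
        if require_verdict:
            hits += evaluate_plate(plate, alpha=alpha).synergistic
        else:
            ys = log_survival_groups(plate)
            _, _, p = bliss_t_test(ys["drug_a"], ys["drug_b"], ys["combination"])
            hits += p < alpha
    return hits / n_plates
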