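"""End-to-end drivers for both experiments on tracking-log inputs.

Thin orchestration over the library modules: simulate writes two-site
logs; experiment 1 runs the strategy x topic x classifier grid and the
confusion analysis; experiment 2 harmonizes the two sites, augments, and
evaluates the multi-label CNN, the intensity classifier and the
attribute–SDoH correlations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import grid as grid_mod
from .cnn import TrainConfig, verify_architecture
from .harmonize import (
    SHARED_ATTRIBUTES,
    SyntheticTravelProvider,
    TravelProvider,
    assign_intensity,
    binarize_strings,
    derive_bins,
    harmonize as harmonize_sites,
    paper_bins,
    travel_augment,
)
from .data_model import impute_missing, parse_tracking_log, write_tracking_log
from .multilabel import attribute_correlations, intensity_classifier, train_eval_multilabel
from .strategies import apply_strategy, instances_to_frame
from .synthetic import CohortConfig, generate_cohort, generate_site_b, ground_truth_report
from .taxonomy import default_taxonomy


def config_hash(params: dict) -> str:
    """Stable short hash identifying a run configuration."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: Path, params: dict, artifacts: list[str]) -> None:
    manifest = {
        "config": params,
        "config_hash": config_hash(params),
        "artifacts": sorted(artifacts),
    }
    (out_dir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, default=str))


def simulate_to_dir(cfg: CohortConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate both sites' logs plus the ground-truth report as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients_a, encounters_a, truth = generate_cohort(cfg)
    patients_b, encounters_b = generate_site_b(cfg)
    paths = {
        "site_a_demographics": out / "site_a_demographics.csv",
        "site_a_encounters": out / "site_a_encounters.csv",
        "site_b_demographics": out / "site_b_demographics.csv",
        "site_b_encounters": out / "site_b_encounters.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    write_tracking_log(
        patients_a, encounters_a, paths["site_a_demographics"], paths["site_a_encounters"]
    )
    write_tracking_log(
        patients_b,
        encounters_b,
        paths["site_b_demographics"],
        paths["site_b_encounters"],
        include_comments=False,
    )
    ground_truth_report(truth).to_csv(paths["ground_truth"], index=False)
    write_manifest(out, asdict(cfg), [p.name for p in paths.values()])
    return paths


def load_site(data_dir: str | Path, site: str = "a", *, drop_unusable: bool = True):
    """Parse and impute one site's log pair from a directory."""
    data_dir = Path(data_dir)
    patients, encounters = parse_tracking_log(
        data_dir / f"site_{site}_demographics.csv",
        data_dir / f"site_{site}_encounters.csv",
    )
    patients, encounters, _ = impute_missing(
        patients, encounters, drop_encounters_missing_text_or_codes=drop_unusable
    )
    return patients, encounters


def run_exp1(
    patients,
    encounters,
    *,
    strategies=("s1", "s2", "s3", "s4", "s5", "s6"),
    k_grid=(5, 10, 15, 20, 25, 30),
    algorithms=grid_mod.ALGORITHMS,
    folds: int = 10,
    seed: int = 0,
    topic_fit: str = "fold",
    topic_max_iter: int = 500,
):
    """Run the model grid; return (results, heatmap table, best result)."""
    configs = grid_mod.enumerate_configs(tuple(strategies), tuple(k_grid), tuple(algorithms))
    tables = {
        s: instances_to_frame(apply_strategy(patients, encounters, s), patients)
        for s in dict.fromkeys(c.strategy for c in configs)
    }
    topic_cache: dict = {}
    results = [
        grid_mod.run_config_cv(
            tables[c.strategy],
            c,
            folds=folds,
            seed=seed,
            topic_fit=topic_fit,
            topic_max_iter=topic_max_iter,
            topic_cache=topic_cache,
        )
        for c in configs
    ]
    return results, grid_mod.heatmap_table(results), grid_mod.best_result(results)


def grouped_confidence_report(cs: grid_mod.ConfusionSummary, m_max: int = 5) -> pd.DataFrame:
    """Row composition and cumulative grouped confidence per prediction row."""
    rows = []
    for cls in cs.classes:
        total = cs.row_total(cls)
        if total == 0:
            continue
        comp = grid_mod.row_composition(cs, cls)
        entry = {
            "predicted_class": cls,
            "row_total": total,
            "top_true_classes": ";".join(c for c, _, _ in comp[:4]),
            "own_pct": next((p for c, _, p in comp if c == cls), 0.0),
        }
        for m in range(1, min(m_max, len(cs.classes)) + 1):
            entry[f"grouped_confidence_m{m}"] = round(
                grid_mod.grouped_confidence(cs, cls, m), 1
            )
        rows.append(entry)
    return pd.DataFrame(rows)


def run_exp2(
    site_a,
    site_b,
    *,
    bins: str = "paper",
    provider: TravelProvider | None = None,
    folds: int = 10,
    seed: int = 0,
    epochs: int = 100,
    include_none_class: bool = True,
):
    """Harmonize, augment, and evaluate experiment 2.

    Returns a dict with the unified table, per-class CNN report, intensity
    accuracy, correlation table and architecture audit.
    """
    taxonomy = default_taxonomy()
    unified = harmonize_sites(site_a, site_b, taxonomy)
    bin_spec = (
        paper_bins() if bins == "paper" else derive_bins(list(unified["encounter_count"]))
    )
    unified = assign_intensity(unified, bin_spec)
    provider = provider or SyntheticTravelProvider()
    unified = travel_augment(unified, provider)

    X, dictionary, Y = binarize_strings(unified, taxonomy, include_none_class=include_none_class)
    keep = [c for c in Y.columns if Y[c].sum() > 0]  # classes present in the cohort
    Y_active = Y[keep]
    report = train_eval_multilabel(
        X,
        Y_active,
        folds=folds,
        seed=seed,
        train_config=TrainConfig(epochs=epochs),
    )
    from .multilabel import build_network

    audit = verify_architecture(build_network(X.shape[1], Y_active.shape[1], seed=seed))

    demo_cols = [
        c
        for c in X.columns
        if any(c.startswith(a) for a in SHARED_ATTRIBUTES)
    ]
    intensity_acc = intensity_classifier(
        X[demo_cols], unified["encounter_range"], folds=folds, seed=seed
    )
    corr_table = pd.concat([X[demo_cols].reset_index(drop=True),
                            Y_active.reset_index(drop=True)], axis=1)
    correlations = attribute_correlations(corr_table, list(Y_active.columns))
    return {
        "unified": unified,
        "bins": bin_spec,
        "feature_dictionary": dictionary,
        "per_class_report": report,
        "architecture_audit": audit,
        "intensity_accuracy": intensity_acc,
        "correlations": correlations,
    }
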