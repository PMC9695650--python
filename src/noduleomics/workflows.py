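"""End-to-end composition helpers: phantom cohort -> features -> selection
-> SVM -> held-out metrics.

These are thin orchestration wrappers over the stage modules, used by the
CLI, the reproduction script and the test suite.  The held-out test split
never reaches selection or training.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .radiomics_engine import DiscretizationConfig, extract_case
from .roi_geometry import DEFAULT_RING_MM, perinodular_ring
from .feature_selection import lasso_stability, SelectionResult
from .svm_pipeline import SvmModel, MetricsReport, train_svm, evaluate
from .synthetic_data import PhantomSpec, generate_cohort
from .volume_io import FeatureTable

logger = logging.getLogger("noduleomics.workflows")


def phantom_feature_table(
    spec: PhantomSpec,
    bin_width_hu: float = 25.0,
    ring_mm: float = DEFAULT_RING_MM,
    train_frac: float = 0.70,
) -> FeatureTable:
    """Generate a phantom cohort and extract 214 features per case.

    The first ``train_frac`` of case indices per class are tagged
    ``train``, the rest ``test`` (a deterministic stratified split).
    The generator's semantic flags (spiculated / subsolid per case) ride
    along in ``table.data.attrs['semantic']`` so they stay out of the
    feature namespace.
    """
    cfg = DiscretizationConfig(bin_width_hu=bin_width_hu)
    n_train = int(round(train_frac * spec.n_per_class))
    rows, semantic = [], []
    for case_id, _, vol, mask, labels in generate_cohort(spec):
        ring = perinodular_ring(mask, vol, ring_mm)
        feats = extract_case(vol, mask, ring, cfg)
        idx = int(case_id[2:])
        split = "train" if idx < n_train else "test"
        rows.append({"case_id": case_id, "label": labels["class"], "split": split, **feats})
        semantic.append(
            {"case_id": case_id, "spiculated": labels["spiculated"],
             "subsolid": labels["subsolid"]}
        )
    table = FeatureTable(pd.DataFrame(rows))
    table.data.attrs["semantic"] = pd.DataFrame(semantic)
    return table


def _top_by_count(selection: SelectionResult, k: int, suffix: str | None = None) -> list[str]:
    items = [
        (f, c) for f, c in selection.selection_counts.items()
        if suffix is None or f.endswith(suffix)
    ]
    items.sort(key=lambda fc: (-fc[1], fc[0]))
    return [f for f, _ in items[:k]]


def select_train_evaluate(
    table: FeatureTable,
    seed: int = 0,
    selection_reps: int = 100,
    svm_reps: int = 100,
    fallback_top: int = 4,
) -> dict:
    """Run selection on the training split, fit both SVM variants, and
    score them on the held-out split.

    If the stability selector returns an empty final set (e.g. on null
    data), the ``fallback_top`` best-counted features are used so the
    classifier stage can still be exercised; the selection result records
    what actually happened.
    """
    train = table.split("train")
    test = table.split("test")
    selection = lasso_stability(train, reps=selection_reps, seed=seed)

    combined_feats = selection.final_features or _top_by_count(selection, fallback_top)
    if not selection.final_features:
        logger.info("empty final selection; falling back to top %d by count", fallback_top)
    intra_feats = [f for f in combined_feats if f.endswith("_intra")]
    if not intra_feats:
        intra_feats = _top_by_count(selection, fallback_top, suffix="_intra")

    model_combined = train_svm(train, combined_feats, reps=svm_reps, seed=seed)
    model_intra = train_svm(train, intra_feats, reps=svm_reps, seed=seed)
    return {
        "selection": selection,
        "model_intra": model_intra,
        "model_combined": model_combined,
        "report_intra": evaluate(model_intra, test),
        "report_combined": evaluate(model_combined, test),
    }
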