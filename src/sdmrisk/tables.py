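"""Published model-selection tables for the whitefly-pest and tomato-host models.

The study this package reproduces compared 12 feature-set × regularization
candidates per species under 10-fold CV and ranked them on the 10% training
omission rate, then the 0% rate, then cross-validated AUC. The printed
tables (with their printed ranks) are shipped as package data so the ranking
rule can be exercised against its published outcome.
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .evaluation import EvaluationRecord


def load_published_table(role: str) -> pd.DataFrame:
    """Load the published candidate table for ``role`` in {'pest', 'host'}."""
    if role not in ("pest", "host"):
        raise ValueError("role must be 'pest' or 'host'")
    ref = importlib.resources.files("sdmrisk.data").joinpath(
        f"published_model_selection_{role}.csv")
    with ref.open() as fh:
        return pd.read_csv(fh)


def published_records(role: str) -> tuple[list[EvaluationRecord], list[int]]:
    """Records in printed-rank order plus the printed ranks themselves."""
    df = load_published_table(role)
    records = [
        EvaluationRecord(features=r.features, rm=float(r.rm),
                         auc_cv_mean=float(r.auc_cv_mean),
                         auc_cv_sd=float(r.auc_cv_sd),
                         or0=float(r.or0), or10=float(r.or10))
        for r in df.itertuples()
    ]
    return records, df["rank"].tolist()
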