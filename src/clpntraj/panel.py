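"""Data model and I/O for three-wave GAD-7/PHQ-9 symptom panels.

A panel holds, for every subject and every wave, the 16 ordinal item
responses (seven anxiety items GAD1..GAD7 and nine depression items
PHQ1..PHQ9, each scored 0-3) together with per-subject baseline
covariates. The wide CSV dialect is one row per subject with item columns
named ``<item>_t<wave>`` (lower case, e.g. ``gad3_t2``); a schema mapping
may rename columns.

Scoring follows the standard screener conventions: scale sums (GAD 0-21,
PHQ 0-27), mean item scores (0-3), and clinical flags at a sum cutoff of
>= 7. Binarization maps each item to presence (score >= 1) / absence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("clpntraj")

GAD_ITEMS: tuple[str, ...] = tuple(f"GAD{i}" for i in range(1, 8))
PHQ_ITEMS: tuple[str, ...] = tuple(f"PHQ{i}" for i in range(1, 10))
NODES: tuple[str, ...] = GAD_ITEMS + PHQ_ITEMS
WAVES: tuple[int, ...] = (1, 2, 3)
DEFAULT_CUTOFF = 7

#: canonical wide-CSV column name for an item at a wave
def item_column(item: str, wave: int) -> str:
    return f"{item.lower()}_t{wave}"


ITEM_COLUMNS: tuple[str, ...] = tuple(
    item_column(item, w) for w in WAVES for item in NODES
)


class SchemaError(ValueError):
    """A required column is missing from the input table."""


class ValidationError(ValueError):
    """A value in the input table violates the panel invariants."""


@dataclass
class PanelDataset:
    """Ordinal item responses indexed by (subject, wave) plus covariates.

    ``items`` is a DataFrame with a (subject_id, wave) MultiIndex and the
    16 columns of :data:`NODES`, values in {0,1,2,3}. ``covariates`` is a
    DataFrame indexed by subject_id (constant across waves).
    """

    items: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.items = self.items[list(NODES)]
        validate_items(self.items)

    @property
    def subjects(self) -> pd.Index:
        return self.items.index.get_level_values(0).unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def wave(self, w: int) -> pd.DataFrame:
        """Item responses at a single wave, indexed by subject."""
        return self.items.xs(w, level=1)


@dataclass
class BinaryPanel:
    """Symptom presence/absence indicators with the same index structure."""

    items: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def subjects(self) -> pd.Index:
        return self.items.index.get_level_values(0).unique()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def wave(self, w: int) -> pd.DataFrame:
        return self.items.xs(w, level=1)


def validate_items(items: pd.DataFrame, lo: int = 0, hi: int = 3) -> None:
    """Raise :class:`ValidationError` naming subject and column on a
    non-integer or out-of-range item score."""
    values = items.to_numpy()
    bad = ~np.isin(values, np.arange(lo, hi + 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        subject = items.index[r][0] if items.index.nlevels > 1 else items.index[r]
        raise ValidationError(
            f"item score out of range [{lo},{hi}] for subject "
            f"{subject!r}, column {items.columns[c]!r}: {values[r, c]!r}"
        )


def read_panel(
    source,
    covariates: list[str] | None = None,
    schema: dict[str, str] | None = None,
    subject_col: str = "subject_id",
) -> PanelDataset:
    """Read a wide CSV (one row per subject) into a :class:`PanelDataset`.

    Parameters
    ----------
    source : path or text stream
        Wide CSV with a header; 48 item columns named per the
        ``<item>_t<wave>`` dialect (overridable through *schema*).
    covariates : list of str
        Names of covariate columns to keep; missing ones raise.
    schema : dict
        Map from canonical column name to the actual column name in the
        file, e.g. ``{"gad1_t1": "GAD01_W1"}``.
    subject_col : str
        Column holding the subject identifier.

    Subjects with any missing item value are dropped (complete-case design)
    with a logged count; unknown columns are ignored with a logged warning.
    """
    wide = pd.read_csv(source)
    schema = schema or {}
    covariates = list(covariates or [])

    def actual(name: str) -> str:
        return schema.get(name, name)

    required = [actual(subject_col)] + [actual(c) for c in ITEM_COLUMNS]
    required += [actual(c) for c in covariates]
    missing = [c for c in required if c not in wide.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    unknown = set(wide.columns) - set(required)
    if unknown:
        logger.warning("ignoring %d unknown column(s): %s", len(unknown), sorted(unknown))

    wide = wide.rename(columns={actual(c): c for c in [subject_col, *ITEM_COLUMNS, *covariates]})
    item_block = wide[list(ITEM_COLUMNS)]
    complete = item_block.notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d subject(s) with incomplete waves", int((~complete).sum()))
        wide = wide.loc[complete]

    records = []
    for w in WAVES:
        block = wide[[item_column(i, w) for i in NODES]].copy()
        block.columns = list(NODES)
        block.index = pd.MultiIndex.from_arrays(
            [wide[subject_col], np.full(len(wide), w)], names=["subject_id", "wave"]
        )
        records.append(block)
    items = pd.concat(records).sort_index().astype(int)

    cov = wide.set_index(subject_col)[covariates] if covariates else pd.DataFrame(
        index=pd.Index(wide[subject_col], name="subject_id")
    )
    cov.index.name = "subject_id"
    return PanelDataset(items=items, covariates=cov)


def write_panel(data: PanelDataset | BinaryPanel, target) -> None:
    """Write a panel back to the wide one-row-per-subject CSV dialect."""
    blocks = []
    for w in WAVES:
        block = data.wave(w).copy()
        block.columns = [item_column(i, w) for i in block.columns]
        blocks.append(block)
    wide = pd.concat(blocks, axis=1)
    if len(data.covariates.columns):
        wide = wide.join(data.covariates)
    wide.index.name = "subject_id"
    wide.reset_index().to_csv(target, index=False)


def score_panel(data: PanelDataset, cutoff: int = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Scale sums, mean item scores and clinical flags per subject-wave.

    Returns a DataFrame indexed by (subject_id, wave) with columns
    ``gad_sum``, ``phq_sum``, ``gad_mean``, ``phq_mean``, ``anxious``,
    ``depressed``; a flag is true iff the scale sum is >= *cutoff*.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    gad = data.items[list(GAD_ITEMS)].sum(axis=1)
    phq = data.items[list(PHQ_ITEMS)].sum(axis=1)
    return pd.DataFrame(
        {
            "gad_sum": gad,
            "phq_sum": phq,
            "gad_mean": gad / len(GAD_ITEMS),
            "phq_mean": phq / len(PHQ_ITEMS),
            "anxious": gad >= cutoff,
            "depressed": phq >= cutoff,
        }
    )


def binarize(data: PanelDataset) -> BinaryPanel:
    """Map item scores to presence indicators (0 = absent, 1-3 = present)."""
    return BinaryPanel(items=(data.items >= 1).astype(int), covariates=data.covariates)
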