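"""Assembly of the immune feature table: frequencies plus functional features.

Two feature classes are derived per sample (one animal at one timepoint):

* frequency features — one per population, the gated percentages from
  :func:`orthoimmune.gating.compute_frequencies`;
* functional features — one per population x functional marker, defined as
  the sample's per-population arcsinh median minus a baseline reference
  median (pooled over baseline samples by default, or per sex).

Under the default panel (21 populations, 12 functional markers) this yields
21 x (1 + 12) = 273 features, each annotated with its population, marker,
feature class and innate/adaptive compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .gating import (
    EventTable,
    GatingScheme,
    META_COLUMNS,
    compartment_of,
    compute_frequencies,
)
from .panel import FREQUENCY, PanelConfig

logger = logging.getLogger(__name__)

POOLED = "pooled-baseline"
PER_SEX = "per-sex-baseline"
BASELINE_TIMEPOINT = "BL"


def feature_name(population: str, marker: str) -> str:
    return f"{population}|{marker}"


@dataclass
class FeatureTable:
    """Samples x features matrix with per-sample metadata and annotations.

    ``values``: DataFrame indexed by sample_id, one column per feature.
    ``meta``: DataFrame indexed by sample_id with animal_id, sex, timepoint.
    ``annotations``: DataFrame indexed by feature name with population,
    marker (or FREQUENCY), feature_class and compartment.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same sample index")
        if list(self.values.columns) != list(self.annotations.index):
            raise ValueError("annotations must match feature columns in order")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated feature names")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def at_timepoint(self, timepoint: str) -> "FeatureTable":
        keep = self.meta.index[self.meta["timepoint"] == timepoint]
        return FeatureTable(self.values.loc[keep], self.meta.loc[keep], self.annotations)

    def select_class(self, feature_class: str) -> "FeatureTable":
        cols = self.annotations.index[self.annotations["feature_class"] == feature_class]
        return FeatureTable(self.values[list(cols)], self.meta,
                            self.annotations.loc[list(cols)])

    def sex(self) -> pd.Series:
        return self.meta["sex"]

    # -- delimited-text round trip -----------------------------------------

    def write(self, values_path, annotations_path) -> None:
        out = pd.concat([self.meta, self.values], axis=1)
        out.to_csv(values_path, index=True, index_label="sample_id")
        self.annotations.to_csv(annotations_path, index=True, index_label="feature")

    @classmethod
    def read(cls, values_path, annotations_path) -> "FeatureTable":
        df = pd.read_csv(values_path, index_col="sample_id")
        ann = pd.read_csv(annotations_path, index_col="feature")
        meta_cols = [c for c in META_COLUMNS if c != "sample_id" and c in df.columns]
        meta = df[meta_cols]
        values = df[[c for c in df.columns if c not in meta_cols]]
        return cls(values=values, meta=meta, annotations=ann.loc[list(values.columns)])


# ---------------------------------------------------------------------------
# Baseline references and functional features
# ---------------------------------------------------------------------------

def _per_population_medians(
    events: EventTable, labels: pd.Series, markers: list[str]
) -> pd.DataFrame:
    """Median arcsinh per (sample, population, marker); long -> wide samples."""
    arcs = events.arcsinh(markers)
    arcs = arcs.assign(
        sample_id=events.data["sample_id"].to_numpy(),
        population=labels.to_numpy(),
    )
    med = arcs.groupby(["sample_id", "population"], sort=True)[markers].median()
    return med


def compute_baseline_reference(
    events: EventTable,
    labels: pd.Series,
    policy: str = POOLED,
    baseline_timepoint: str = BASELINE_TIMEPOINT,
) -> pd.DataFrame:
    """Reference arcsinh median per population x functional marker.

    Medians are taken over *all cells* of a population pooled across the
    baseline samples of the policy's stratum (every baseline sample under
    the pooled policy; per sex otherwise), not over per-sample medians.

    Returns a DataFrame indexed by population (pooled) or by
    (sex, population) MultiIndex (per-sex), one column per functional marker.
    An empty population at baseline yields NaN (missing-reference flag).
    """
    if policy not in (POOLED, PER_SEX):
        raise ValueError(f"unknown baseline policy {policy!r}")
    markers = list(events.panel.functional_markers)
    is_bl = events.data["timepoint"].to_numpy() == baseline_timepoint
    if not is_bl.any():
        raise ValueError(f"no samples at baseline timepoint {baseline_timepoint!r}")
    arcs = events.arcsinh(markers).loc[is_bl]
    arcs = arcs.assign(population=labels.to_numpy()[is_bl])
    if policy == POOLED:
        ref = arcs.groupby("population", sort=True)[markers].median()
    else:
        arcs = arcs.assign(sex=events.data["sex"].to_numpy()[is_bl])
        ref = arcs.groupby(["sex", "population"], sort=True)[markers].median()
    empties = ref[markers].isna().any(axis=1)
    if empties.any():
        logger.warning("missing baseline reference for: %s", list(ref.index[empties]))
    return ref


def derive_functional_features(
    events: EventTable,
    labels: pd.Series,
    reference: pd.DataFrame,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Functional features: per-sample arcsinh median minus baseline reference.

    Returns samples x (population|marker) DataFrame; a population absent from
    a sample gives NaN (explicit missing value).
    """
    markers = list(events.panel.functional_markers)
    per_sex = isinstance(reference.index, pd.MultiIndex)
    med = _per_population_medians(events, labels, markers)
    if populations is None:
        populations = sorted({p for _, p in med.index if p != "UNGATED"})

    samples = events.samples
    index = pd.Index(list(samples.index), name="sample_id")
    cols: dict[str, pd.Series] = {}
    for pop in populations:
        for m in markers:
            col = pd.Series(np.nan, index=index)
            try:
                vals = med.xs(pop, level="population")[m]
            except KeyError:
                vals = pd.Series(dtype=float)
            col.loc[vals.index.intersection(col.index)] = vals
            if per_sex:
                ref_vals = samples["sex"].map(
                    lambda s, pop=pop, m=m: reference[m].get((s, pop), np.nan)
                )
                col = col - ref_vals
            else:
                ref_val = reference[m].get(pop, np.nan)
                col = col - ref_val
            cols[feature_name(pop, m)] = col
    return pd.DataFrame(cols, index=index)


def assemble_feature_table(
    frequencies: pd.DataFrame,
    functional: pd.DataFrame,
    meta: pd.DataFrame,
    panel: PanelConfig,
    populations: list[str],
) -> FeatureTable:
    """Combine frequency and functional features into one annotated table.

    Column order is population-major with the frequency feature first, then
    functional markers in panel order: n_populations x (1 + n_functional)
    columns in total.
    """
    if not frequencies.index.sort_values().equals(functional.index.sort_values()):
        raise ValueError("frequency and functional tables cover different samples")
    functional = functional.reindex(frequencies.index)
    meta = meta.reindex(frequencies.index)
    if meta[["sex", "timepoint"]].isna().any().any():
        raise ValueError("metadata does not cover all samples")

    cols = {}
    ann_rows = []
    for pop in populations:
        fname = feature_name(pop, FREQUENCY)
        if pop not in frequencies.columns:
            raise ValueError(f"missing frequency column for population {pop!r}")
        cols[fname] = frequencies[pop]
        ann_rows.append({"feature": fname, "population": pop, "marker": FREQUENCY,
                         "feature_class": "frequency", "compartment": compartment_of(pop)})
        for m in panel.functional_markers:
            fn = feature_name(pop, m)
            if fn not in functional.columns:
                raise ValueError(f"missing functional column {fn!r}")
            cols[fn] = functional[fn]
            ann_rows.append({"feature": fn, "population": pop, "marker": m,
                             "feature_class": "functional",
                             "compartment": compartment_of(pop)})
    values = pd.DataFrame(cols)
    annotations = pd.DataFrame(ann_rows).set_index("feature")
    return FeatureTable(values=values, meta=meta[["animal_id", "sex", "timepoint"]],
                        annotations=annotations)


def derive_feature_table(
    events: EventTable,
    labels: pd.Series,
    scheme: GatingScheme,
    baseline_policy: str = POOLED,
    baseline_timepoint: str = BASELINE_TIMEPOINT,
) -> FeatureTable:
    """End-to-end feature derivation from gated events."""
    freqs = compute_frequencies(events, labels, scheme)
    ref = compute_baseline_reference(events, labels, policy=baseline_policy,
                                     baseline_timepoint=baseline_timepoint)
    func = derive_functional_features(events, labels, ref,
                                      populations=list(scheme.leaves))
    meta = events.samples.set_index("sample_id", drop=False) \
        if "sample_id" not in events.samples.index.names else events.samples
    return assemble_feature_table(freqs, func, meta, events.panel,
                                  populations=list(scheme.leaves))


def impute_missing(table: FeatureTable) -> tuple[FeatureTable, int]:
    """Impute missing features by feature-wise median within timepoint.

    Features still missing after that (a population empty in every sample of
    a timepoint) fall back to the overall feature median, then to zero.
    Returns the imputed table and the number of imputed cells (logged).
    """
    values = table.values.copy()
    n_missing = int(values.isna().to_numpy().sum())
    if n_missing:
        tp = table.meta["timepoint"]
        values = values.groupby(tp, group_keys=False).apply(
            lambda g: g.fillna(g.median())
        )
        values = values.fillna(table.values.median()).fillna(0.0)
        values = values.reindex(table.values.index)
        logger.info("imputed %d missing feature values", n_missing)
    return FeatureTable(values, table.meta, table.annotations), n_missing
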