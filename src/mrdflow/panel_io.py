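"""Single-tube panel definition, event-level I/O and scale transforms.

The analysis operates on a one-tube, eight-antibody AML MRD panel: three
scatter parameters (FSC-A, FSC-H, SSC-A) plus CD7, CD13, CD33, CD34, CD45,
CD56, CD117 and HLA-DR.  Events are assumed compensated upstream; intensities
arrive on an arbitrary linear scale and are mapped to a stable display scale
(asinh with per-marker cofactor) before any fixed threshold is applied.
Synthetic data generated directly on the transformed scale uses the identity
transform.

Supported event sources are FCS 3.0/3.1 files and plain CSV tables with a
header row naming the channels; instrument channel names are mapped to the
logical marker names through a :class:`MarkerPanel`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical marker order used by every event matrix in the package.
MARKERS: tuple[str, ...] = (
    "FSC-A", "FSC-H", "SSC-A",
    "CD7", "CD13", "CD33", "CD34", "CD45", "CD56", "CD117", "HLA-DR",
)

SCATTER_MARKERS: tuple[str, ...] = ("FSC-A", "FSC-H", "SSC-A")

#: The eight monoclonal-antibody targets of the one-tube panel.
ANTIBODY_MARKERS: tuple[str, ...] = tuple(
    m for m in MARKERS if m not in SCATTER_MARKERS
)

SAMPLE_KINDS: tuple[str, ...] = ("diagnosis", "followup", "lfc")

#: Leukemia-free control subcohorts: bone-marrow donors, ALL in molecular CR,
#: hip-surgery patients and untreated primary CNS lymphoma.
LFC_COHORTS: tuple[str, ...] = ("ALL_molCR", "BMD", "PCNSL", "hip_surgery")


class PanelError(ValueError):
    """A required channel is missing or the channel map is inconsistent."""


class TransformError(ValueError):
    """Invalid transform specification."""


@dataclass(frozen=True)
class MarkerPanel:
    """Maps instrument channel names onto the logical panel markers.

    ``channel_map`` is instrument-channel-name -> logical-marker-name.  Every
    logical marker must be the target of exactly one channel.  The exact
    fluorochrome/detector assignment is instrument specific, so the map is
    user supplied; :meth:`identity` covers tables already using logical names.
    """

    channel_map: Mapping[str, str]

    def __post_init__(self) -> None:
        targets = list(self.channel_map.values())
        for marker in MARKERS:
            n = targets.count(marker)
            if n == 0:
                raise PanelError(f"missing channel {marker}")
            if n > 1:
                raise PanelError(f"marker {marker} mapped from {n} channels")

    @classmethod
    def identity(cls) -> "MarkerPanel":
        return cls({m: m for m in MARKERS})

    def resolve(self, columns: list[str]) -> dict[str, str]:
        """Return {column -> logical marker} for the given source columns.

        Raises :class:`PanelError` naming the first logical marker that no
        source column provides.
        """
        mapping = {c: self.channel_map[c] for c in columns if c in self.channel_map}
        present = set(mapping.values())
        for marker in MARKERS:
            if marker not in present:
                raise PanelError(f"missing channel {marker}")
        return mapping


@dataclass
class EventMatrix:
    """Per-event scatter and marker intensities for one sample.

    ``values`` is an (n_events x 11) float array in :data:`MARKERS` order.
    All intensities must be finite; the matrix may not be empty.
    """

    values: np.ndarray
    sample_id: str = "sample"
    sample_kind: str = "followup"
    cohort_label: str | None = None

    markers: tuple[str, ...] = field(default=MARKERS, init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != len(MARKERS):
            raise ValueError(
                f"event matrix must be (n, {len(MARKERS)}); got {self.values.shape}"
            )
        if self.values.shape[0] < 1:
            raise ValueError("event matrix must contain at least one event")
        if not np.isfinite(self.values).all():
            raise ValueError("event matrix contains non-finite intensities")
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValueError(f"sample_kind must be one of {SAMPLE_KINDS}")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    def marker(self, name: str) -> np.ndarray:
        """Column view for one marker."""
        return self.values[:, MARKERS.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(MARKERS))

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        sample_id: str = "sample",
        sample_kind: str = "followup",
        cohort_label: str | None = None,
    ) -> "EventMatrix":
        missing = [m for m in MARKERS if m not in df.columns]
        if missing:
            raise PanelError(f"missing channel {missing[0]}")
        return cls(
            df[list(MARKERS)].to_numpy(dtype=np.float64),
            sample_id=sample_id,
            sample_kind=sample_kind,
            cohort_label=cohort_label,
        )


def read_events(
    path: str | Path,
    panel: MarkerPanel | None = None,
    sample_id: str | None = None,
    sample_kind: str = "followup",
    cohort_label: str | None = None,
) -> EventMatrix:
    """Read an event matrix from an FCS 3.0/3.1 file or a CSV table.

    The file type is sniffed from the leading bytes (``FCS`` magic).  Columns
    are renamed to logical marker names through ``panel`` (identity map by
    default); a source lacking a required channel raises :class:`PanelError`.
    """
    path = Path(path)
    panel = panel or MarkerPanel.identity()
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic == b"FCS":
        from .fcs import read_fcs

        df, _meta = read_fcs(path)
    else:
        df = pd.read_csv(path)
    mapping = panel.resolve(list(df.columns))
    df = df.rename(columns=mapping)
    return EventMatrix.from_dataframe(
        df,
        sample_id=sample_id or path.stem,
        sample_kind=sample_kind,
        cohort_label=cohort_label,
    )


def write_events_csv(events: EventMatrix, path: str | Path) -> None:
    """Write events as a CSV table with logical marker names as header."""
    events.to_dataframe().to_csv(path, index=False)


def _default_cofactors() -> dict[str, float]:
    return {m: 150.0 for m in ANTIBODY_MARKERS}


@dataclass(frozen=True)
class TransformSpec:
    """Per-marker monotone display transform.

    ``asinh`` applies x -> asinh(x / cofactor) to the antibody markers;
    scatter channels are always left on the linear scale.  ``identity``
    leaves everything untouched (for data generated on the transformed
    scale).  Cofactors must be strictly positive so the map is strictly
    monotone.
    """

    kind: str = "asinh"
    cofactors: Mapping[str, float] = field(default_factory=_default_cofactors)

    def __post_init__(self) -> None:
        if self.kind not in ("asinh", "identity"):
            raise TransformError(f"unknown transform kind {self.kind!r}")
        if self.kind == "asinh":
            for m in ANTIBODY_MARKERS:
                c = self.cofactors.get(m)
                if c is None:
                    raise TransformError(f"no cofactor for marker {m}")
                if not (c > 0 and np.isfinite(c)):
                    raise TransformError(
                        f"cofactor for {m} must be positive and finite (got {c})"
                    )

    def apply(self, events: EventMatrix) -> EventMatrix:
        if self.kind == "identity":
            return dataclasses.replace(events, values=events.values.copy())
        values = events.values.copy()
        for m in ANTIBODY_MARKERS:
            j = MARKERS.index(m)
            values[:, j] = np.arcsinh(values[:, j] / self.cofactors[m])
        return dataclasses.replace(events, values=values)


def transform(events: EventMatrix, spec: TransformSpec) -> EventMatrix:
    """Apply a :class:`TransformSpec`; scatter channels are untouched."""
    return spec.apply(events)
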