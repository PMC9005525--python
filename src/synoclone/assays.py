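"""Closed-form functional-assay scores and small-sample paired comparisons.

Three readouts from the clinical/wet-lab side of the study design:

* **Percent suppression** of responder T cells by Tregs:
  ``100 - 100 * (% responding with Treg) / (% responding without Treg)``.
  Negative values (enhancement) are returned as-is.
* **Migration ratio**: bead-standardized migrated-cell events with
  chemokine over without; invariant to rescaling both bead spikes.
* **CDAI**, the clinical disease activity index: patient global (0-10) +
  physician global (0-10) + swollen (0-28) + tender (0-28) joint counts,
  banded as remission (0-2.8), low (2.9-10.0), moderate (10.1-22.0), and
  high (>22).  The component maxima make the attainable total 0-76.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import SynocloneError
from .stats import paired_t, wilcoxon_signed_rank


@dataclass
class SuppressionAssay:
    pct_with_treg: float
    pct_without_treg: float
    readout: str = "proliferation"

    def __post_init__(self) -> None:
        for name in ("pct_with_treg", "pct_without_treg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise SynocloneError(f"{name} must lie in [0, 100], got {v}")
        if self.readout not in {"proliferation", "IFNG", "IL2"}:
            raise SynocloneError(f"unknown readout: {self.readout}")


@dataclass
class MigrationAssay:
    events_chemokine: int
    events_control: int
    beads_chemokine: int
    beads_control: int

    def __post_init__(self) -> None:
        for name in ("events_chemokine", "events_control"):
            if getattr(self, name) < 0:
                raise SynocloneError(f"{name} must be >= 0")
        for name in ("beads_chemokine", "beads_control"):
            if getattr(self, name) <= 0:
                raise SynocloneError(f"{name} must be > 0")


CDAI_BANDS = [
    ("remission", 0.0, 2.8),
    ("low", 2.8, 10.0),
    ("moderate", 10.0, 22.0),
    ("high", 22.0, float("inf")),
]


@dataclass
class CdaiScore:
    patient_global: float
    physician_global: float
    swollen_joints: int
    tender_joints: int
    total: float
    band: str


def percent_suppression(assay: SuppressionAssay) -> float:
    """100 - 100 * with/without; antitone in pct_with_treg, may be negative."""
    if assay.pct_without_treg == 0:
        raise SynocloneError("percent suppression undefined: no response without Tregs")
    return 100.0 - 100.0 * assay.pct_with_treg / assay.pct_without_treg


def migration_ratio(assay: MigrationAssay) -> float:
    """(events_chemokine / beads_chemokine) / (events_control / beads_control)."""
    if assay.events_control == 0:
        raise SynocloneError("migration ratio undefined: no migration in control")
    return (assay.events_chemokine / assay.beads_chemokine) / (
        assay.events_control / assay.beads_control
    )


def cdai(
    patient_global: float,
    physician_global: float,
    swollen: int,
    tender: int,
) -> CdaiScore:
    """Total CDAI and its activity band.

    Bands are half-open on the lower edge: [0, 2.8] remission,
    (2.8, 10.0] low, (10.0, 22.0] moderate, (22, inf) high — so a total
    of exactly 22 is moderate and anything above is high.
    """
    for name, v, hi in (
        ("patient_global", patient_global, 10),
        ("physician_global", physician_global, 10),
        ("swollen", swollen, 28),
        ("tender", tender, 28),
    ):
        if not 0 <= v <= hi:
            raise SynocloneError(f"{name} outside [0, {hi}]: {v}")
    total = float(patient_global + physician_global + swollen + tender)
    if total <= 2.8:
        band = "remission"
    elif total <= 10.0:
        band = "low"
    elif total <= 22.0:
        band = "moderate"
    else:
        band = "high"
    return CdaiScore(patient_global, physician_global, swollen, tender, total, band)


def paired_compare(before, after, test: str = "wilcoxon_one_sided", alternative: str = "less"):
    """Paired comparison of before/after vectors.

    ``wilcoxon_one_sided``: one-sided Wilcoxon matched-pairs signed-rank
    (exact for <= 15 untied pairs); ``t_paired_two_sided``: two-sided
    paired t.  Returns (statistic, p).
    """
    if test == "wilcoxon_one_sided":
        return wilcoxon_signed_rank(before, after, alternative=alternative)
    if test == "t_paired_two_sided":
        return paired_t(before, after)
    raise SynocloneError(f"unknown test: {test}")
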