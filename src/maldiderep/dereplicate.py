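"""Dereplication of a spectrum set into operational isolation units (OIUs).

The pipeline has five steps:

1. *Quality control.*  A spectrum is good quality (green) if it has at least
   five peaks with S/N above 30; one to four such peaks makes it low quality
   (orange); none makes it poor quality (red).  Only green spectra enter the
   USF comparison.
2. *USF matrix.*  Every pair of green spectra is compared (see
   :mod:`maldiderep.usf`) to count directional unique spectral features.
3. *Reference selection.*  Spectra are ranked by total USF count
   (most-unique first, ties by id); walking down the ranking, a spectrum
   becomes a reference iff it shows at least one USF against every spectrum
   evaluated before it.  Pre-existing references from an earlier run may be
   prepended and are references unconditionally, which makes incremental
   dereplication stable.
4. *OIU assignment.*  Every remaining green spectrum joins the
   lowest-ranked reference against which it has zero USFs; a reference and
   the spectra assigned to it form one OIU.
5. *Low-quality rescue.*  Orange and red spectra are matched to every
   reference whose peak list gives a Dice coefficient above 0.70 (matching
   at the same ppm window), providing abundance bookkeeping without letting
   weak spectra found OIUs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .io import PeakList, SpectrumDataset
from .usf import DereplicationParams, USFMatrix, build_usf_matrix, match_peaks

logger = logging.getLogger(__name__)

__all__ = [
    "QualityClass",
    "DereplicationResult",
    "classify_quality",
    "select_references",
    "assign_spectra",
    "dice_coefficient",
    "match_low_quality",
    "dereplicate",
    "audit_result",
    "Dereplicator",
]


@dataclass(frozen=True)
class QualityClass:
    """Traffic-light quality of one spectrum from its strong-peak count."""

    spectrum_id: str
    quality_class: str  # "green" | "orange" | "red"
    n_strong_peaks: int


@dataclass
class DereplicationResult:
    """Everything a finished run produced.

    references are in selection order; ``assignments`` maps every green
    spectrum (references included, mapped to themselves) to its reference;
    ``oius`` groups members per reference; ``low_quality_matches`` records
    all (reference, Dice) pairs above threshold per orange/red spectrum.
    """

    references: list[str]
    assignments: dict[str, str]
    oius: dict[str, list[str]]
    low_quality_matches: dict[str, tuple[tuple[str, float], ...]]
    quality: dict[str, QualityClass]
    params: DereplicationParams
    metadata: object | None = None
    usf_matrix: USFMatrix | None = None

    @property
    def green_ids(self) -> list[str]:
        return sorted(
            s for s, q in self.quality.items() if q.quality_class == "green"
        )

    def oiu_index(self, spectrum_id: str) -> int:
        """Index of the OIU a green spectrum belongs to, in reference order."""
        return self.references.index(self.assignments[spectrum_id])


def classify_quality(
    peaks: PeakList, params: DereplicationParams | None = None
) -> QualityClass:
    """Green / orange / red from the number of peaks with S/N strictly > 30."""
    params = params or DereplicationParams()
    n_strong = int(np.sum(peaks.snr > params.snr_threshold))
    if n_strong >= params.min_good_peaks:
        cls = "green"
    elif n_strong >= 1:
        cls = "orange"
    else:
        cls = "red"
    return QualityClass(peaks.spectrum_id, cls, n_strong)


def _evaluation_order(usf: USFMatrix, preexisting: Sequence[str]) -> list[str]:
    pre = list(preexisting)
    missing = [p for p in pre if p not in usf._index]
    if missing:
        raise ValueError(f"pre-existing reference ids not in USF matrix: {missing}")
    rest = [s for s in usf.ids if s not in set(pre)]
    rest.sort(key=lambda s: (-usf.row_sum(s), s))
    return pre + rest


def select_references(
    usf: USFMatrix,
    preexisting: Sequence[str] | None = None,
    compare_to: str = "evaluated",
) -> list[str]:
    """Pick reference spectra by walking the USF-sum ranking.

    A candidate is a reference iff it has >= 1 USF against every spectrum in
    the comparison pool: all previously evaluated spectra (default) or only
    the previously selected references (``compare_to="references"``).
    Pre-existing references are prepended and selected unconditionally.
    """
    if compare_to not in ("evaluated", "references"):
        raise ValueError("compare_to must be 'evaluated' or 'references'")
    pre = list(preexisting) if preexisting else []
    order = _evaluation_order(usf, pre)
    references: list[str] = []
    evaluated: list[str] = []
    for sid in order:
        pool = evaluated if compare_to == "evaluated" else references
        if sid in pre or all(usf.value(sid, p) >= 1 for p in pool):
            references.append(sid)
        evaluated.append(sid)
    return references


def assign_spectra(usf: USFMatrix, references: Sequence[str]) -> dict[str, str]:
    """Map every spectrum to the lowest-index reference it has no USF against.

    References map to themselves.  A non-reference without any zero-USF
    reference indicates an inconsistent selection and raises.
    """
    if not references:
        raise ValueError("references must be non-empty")
    refs = list(references)
    assignments: dict[str, str] = {r: r for r in refs}
    for sid in usf.ids:
        if sid in assignments:
            continue
        for ref in refs:
            if usf.value(sid, ref) == 0:
                assignments[sid] = ref
                break
        else:
            raise RuntimeError(
                f"spectrum {sid!r} has >= 1 USF against every reference; "
                "reference selection was inconsistent (intransitive USF "
                "structure under compare_to='evaluated')"
            )
    return assignments


def dice_coefficient(
    peaks_a: PeakList, peaks_b: PeakList, ppm_window: float
) -> float:
    """Dice coefficient of two peak lists: 2 * matched / (|A| + |B|).

    Matching is the same greedy one-to-one ppm-window matching used for USF
    determination.  Two empty lists give 0 by convention.
    """
    total = len(peaks_a) + len(peaks_b)
    if total == 0:
        return 0.0
    matched = match_peaks(peaks_a, peaks_b, ppm_window).matched
    return 2.0 * len(matched) / total


def match_low_quality(
    low_ids: Sequence[str],
    references: Sequence[str],
    dataset: SpectrumDataset,
    params: DereplicationParams | None = None,
) -> dict[str, tuple[tuple[str, float], ...]]:
    """Match each low-quality spectrum to all references with Dice > threshold.

    The full peak lists are used (no S/N filter): low-quality spectra lack
    strong peaks by definition, and weak shared peaks are exactly the signal
    the rescue step relies on.
    """
    params = params or DereplicationParams()
    out: dict[str, tuple[tuple[str, float], ...]] = {}
    for sid in low_ids:
        hits = []
        for ref in references:
            d = dice_coefficient(
                dataset.peaks(sid), dataset.peaks(ref), params.ppm_window
            )
            if d > params.dice_threshold:
                hits.append((ref, d))
        out[sid] = tuple(hits)
    return out


def dereplicate(
    dataset: SpectrumDataset, params: DereplicationParams | None = None
) -> DereplicationResult:
    """Run the full five-step dereplication on a dataset.

    Deterministic: spectra are processed in sorted-id order and all ties are
    broken by id, so the result does not depend on file enumeration order.
    """
    params = params or DereplicationParams()
    quality = {sid: classify_quality(dataset.peaks(sid), params) for sid in dataset.ids}
    green = [s for s in dataset.ids if quality[s].quality_class == "green"]
    low = [s for s in dataset.ids if quality[s].quality_class != "green"]
    if not green:
        raise ValueError("no spectra pass quality control")
    bad_refs = [r for r in dataset.reference_ids if r not in set(green)]
    if bad_refs:
        raise ValueError(f"pre-existing references fail quality control: {bad_refs}")

    usf = build_usf_matrix(dataset, params, ids=green)
    references = select_references(usf, dataset.reference_ids, params.compare_to)
    assignments = assign_spectra(usf, references)
    oius = {r: sorted(s for s, ref in assignments.items() if ref == r) for r in references}
    low_matches = match_low_quality(low, references, dataset, params)

    n_q = {c: sum(1 for q in quality.values() if q.quality_class == c)
           for c in ("green", "orange", "red")}
    logger.info(
        "dereplicated %d spectra (green=%d orange=%d red=%d) -> %d references / OIUs; "
        "OIU sizes %s",
        len(dataset), n_q["green"], n_q["orange"], n_q["red"], len(references),
        sorted((len(m) for m in oius.values()), reverse=True),
    )
    result = DereplicationResult(
        references=references,
        assignments=assignments,
        oius=oius,
        low_quality_matches=low_matches,
        quality=quality,
        params=params,
        metadata=dataset.metadata,
        usf_matrix=usf,
    )
    audit_result(result, usf)
    return result


def audit_result(result: DereplicationResult, usf: USFMatrix) -> None:
    """Verify the selection/assignment contract on a finished run.

    Every assigned spectrum must have zero USFs against its reference, and
    every later reference must have >= 1 USF against every earlier one
    (pre-existing references are exempt: they are references by fiat).
    """
    for sid, ref in result.assignments.items():
        if sid == ref:
            continue
        if usf.value(sid, ref) != 0:
            raise AssertionError(
                f"audit: {sid!r} assigned to {ref!r} with {usf.value(sid, ref)} USFs"
            )
    in_matrix = [r for r in result.references if r in usf._index]
    for j, later in enumerate(in_matrix):
        for earlier in in_matrix[:j]:
            if usf.value(later, earlier) < 1:
                raise AssertionError(
                    f"audit: reference {later!r} has 0 USFs vs earlier reference "
                    f"{earlier!r}"
                )


class Dereplicator(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator wrapping :func:`dereplicate`.

    Parameters mirror :class:`~maldiderep.usf.DereplicationParams`.  After
    ``fit(dataset)`` the fitted attributes hold the run outcome:

    - ``references_``: reference spectrum ids in selection order
    - ``assignments_``: green spectrum id -> reference id
    - ``oius_``: reference id -> member ids
    - ``labels_``: OIU index per ``dataset.ids`` entry (-1 for low quality)
    - ``result_``: the full :class:`DereplicationResult`
    - ``usf_matrix_``: the green-spectrum USF matrix
    """

    def __init__(
        self,
        ppm_window: float = 700.0,
        local_ppmc_threshold: float = 0.50,
        snr_threshold: float = 30.0,
        min_good_peaks: int = 5,
        dice_threshold: float = 0.70,
        ppmc_halfwidth_factor: float = 2.0,
        compare_to: str = "evaluated",
    ):
        self.ppm_window = ppm_window
        self.local_ppmc_threshold = local_ppmc_threshold
        self.snr_threshold = snr_threshold
        self.min_good_peaks = min_good_peaks
        self.dice_threshold = dice_threshold
        self.ppmc_halfwidth_factor = ppmc_halfwidth_factor
        self.compare_to = compare_to

    def _make_params(self) -> DereplicationParams:
        return DereplicationParams(**self.get_params())

    def fit(self, X: SpectrumDataset, y=None) -> "Dereplicator":
        params = self._make_params()
        result = dereplicate(X, params)
        self.result_ = result
        self.references_ = list(result.references)
        self.assignments_ = dict(result.assignments)
        self.oius_ = {r: list(m) for r, m in result.oius.items()}
        self.usf_matrix_ = result.usf_matrix
        ref_index = {r: k for k, r in enumerate(result.references)}
        self.labels_ = np.array(
            [
                ref_index[result.assignments[sid]]
                if sid in result.assignments
                else -1
                for sid in X.ids
            ],
            dtype=int,
        )
        return self

    def fit_predict(self, X: SpectrumDataset, y=None) -> np.ndarray:
        return self.fit(X).labels_
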