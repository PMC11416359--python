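"""End-to-end convenience wrappers: phantom/specimen -> paired analysis."""

from __future__ import annotations

from typing import Iterable

from .agreement import PairedMeasurements, concat_pairs, pair_records
from .correspondence import SliceCorrespondence, match_slides
from .measure import measure_histology, measure_us
from .model import LabelVolume, MeasurementRecord, SlideStack
from .phantom import PhantomSpecimen

__all__ = ["process_specimen", "specimen_pairs", "cohort_pairs"]


def process_specimen(
    volume: LabelVolume,
    stack: SlideStack,
    landmarks: dict,
    specimen: str = "specimen",
    modality: str = "us-manual",
    window: float = 4.0,
) -> tuple[MeasurementRecord, MeasurementRecord, SliceCorrespondence]:
    """Match, then measure both modalities of one specimen."""
    corr = match_slides(volume, stack, window=window, specimen=specimen)
    us_rec = measure_us(
        volume, corr, landmarks, stack.orientation,
        specimen=specimen, modality=modality,
    )
    histo_rec = measure_histology(stack, specimen=specimen)
    return us_rec, histo_rec, corr


def specimen_pairs(spec: PhantomSpecimen, **kwargs) -> PairedMeasurements:
    us_rec, histo_rec, _ = process_specimen(
        spec.volume, spec.stack, spec.landmarks, specimen=spec.specimen, **kwargs
    )
    return pair_records(us_rec, histo_rec)


def cohort_pairs(specimens: Iterable[PhantomSpecimen], **kwargs) -> PairedMeasurements:
    return concat_pairs([specimen_pairs(s, **kwargs) for s in specimens])
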