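"""End-to-end convenience: recordings -> SL networks -> feature dataset."""

from __future__ import annotations

from .connectivity import SLParams, default_sl_params, subject_connectivity
from .graphmetrics import feature_vector
from .model_validation import CohortDataset, SubjectRecord
from .preprocess import BROADBAND, FrequencyBand, bandpass
from .recording import EpochedRecording
from .synthetic import CohortSpec, generate_cohort

__all__ = ["features_for_subject", "features_from_recordings", "features_from_spec"]


def features_for_subject(
    recording: EpochedRecording,
    band: FrequencyBand = BROADBAND,
    params: SLParams | None = None,
    filter_band: bool = True,
):
    """Band-filter one subject, average per-epoch SL, extract 18 features."""
    if params is None:
        params = default_sl_params(band, recording.fs)
    rec = bandpass(recording, band) if filter_band else recording
    W = subject_connectivity(rec, params)
    return feature_vector(W)


def features_from_recordings(
    labelled_recordings: list[tuple[EpochedRecording, str]],
    band: FrequencyBand = BROADBAND,
    params: SLParams | None = None,
    filter_band: bool = True,
) -> CohortDataset:
    """Feature dataset for a labelled collection of recordings."""
    subjects = [
        SubjectRecord(
            subject_id=rec.subject_id,
            features=features_for_subject(rec, band, params, filter_band),
            group=group,
        )
        for rec, group in labelled_recordings
    ]
    return CohortDataset(subjects, band=band)


def features_from_spec(
    spec: CohortSpec,
    band: FrequencyBand = BROADBAND,
    params: SLParams | None = None,
    filter_band: bool = True,
) -> CohortDataset:
    """Generate a synthetic cohort and run it through the feature pipeline."""
    return features_from_recordings(
        generate_cohort(spec), band=band, params=params, filter_band=filter_band
    )
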