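"""End-to-end per-specimen processing and cohort analysis.

Chains the pipeline stages on one specimen: autofluorescence correction,
vessel segmentation (a trained U-Net via Hann-stitched chunked inference,
or the model-free hysteresis bootstrap), isotropic resampling, graph and
feature extraction, region delineation from the reporter channel, segment
assignment and the per-animal summary. ``analyze_cohort`` maps this over
a labeled phantom cohort and runs the group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .analysis import assign_segments, group_comparison_report, summarize_animal
from .phantom import PhantomDataset
from .preprocess import PreprocessParams, preprocess_bundle
from .regions import (
    RegionLabelVolume,
    RegionParams,
    classify_regions,
    combine_tumor_masks,
    hypoxia_threshold,
    tumor_from_reporter,
)
from .segmentation.infer import chunked_inference, postprocess
from .segmentation.preseg import hysteresis_preseg
from .vesselgraph import VesselGraph, extract_graph, to_isotropic
from .volume import ImageVolume, VolumeBundle


@dataclass
class SpecimenResult:
    animal_id: str
    group: str
    table: pd.DataFrame
    regions: RegionLabelVolume
    graph: VesselGraph
    summary: dict


def segment_vessels(
    vessel: ImageVolume,
    model=None,
    chunk: int = 64,
    hysteresis_low: float = 1.5,
    hysteresis_high: float = 2.5,
) -> np.ndarray:
    """Binary vessel mask: deep model when given, hysteresis bootstrap otherwise."""
    if model is not None:
        prob = chunked_inference(model, vessel, chunk=chunk)
        return postprocess(prob)
    seg = hysteresis_preseg(vessel, hysteresis_low, hysteresis_high)
    return postprocess(seg.astype(float))


def process_specimen(
    animal_id: str,
    group: str,
    channels: VolumeBundle,
    vessel_model=None,
    preprocess_params: PreprocessParams | None = None,
    region_params: RegionParams | None = None,
    manual_add: np.ndarray | None = None,
    manual_remove: np.ndarray | None = None,
) -> SpecimenResult:
    """Run the full analysis chain on one specimen's three channels."""
    pp = preprocess_params or PreprocessParams(k=16)
    rp = region_params or RegionParams()

    vessel_c, reporter_c, exclusion = preprocess_bundle(
        channels.vessel, channels.autofluorescence, channels.reporter, pp
    )

    seg = segment_vessels(vessel_c, model=vessel_model)
    seg_iso, spacing_iso = to_isotropic(seg, vessel_c.spacing)
    graph = extract_graph(seg_iso, spacing_iso)

    tumor = combine_tumor_masks(
        None, tumor_from_reporter(reporter_c, rp), manual_add, manual_remove
    )
    healthy = ~tumor & ~exclusion
    thr = hypoxia_threshold(reporter_c, healthy, rp)
    regions = classify_regions(tumor, reporter_c, thr, excluded=exclusion)

    # regions live on the original grid; resample to the graph's isotropic grid
    factor = seg_iso.shape[0] // seg.shape[0]
    regions_iso = RegionLabelVolume(
        np.repeat(regions.labels, factor, axis=0), spacing_iso,
        regions.provenance, regions.threshold,
    )

    table = assign_segments(graph, regions_iso, animal_id=animal_id, group=group)
    summary = summarize_animal(animal_id, group, table, regions_iso)
    return SpecimenResult(animal_id, group, table, regions_iso, graph, summary)


def analyze_cohort(
    datasets: list[PhantomDataset],
    control: str,
    vessel_model=None,
    **kwargs,
):
    """Process every specimen of a cohort and compare groups to control."""
    results = [
        process_specimen(d.animal_id, d.group, d.channels, vessel_model=vessel_model, **kwargs)
        for d in datasets
    ]
    summaries = pd.DataFrame([r.summary for r in results])
    tables = {}
    for r in results:
        tables.setdefault(r.group, []).append(r.table)
    pooled = {g: pd.concat(ts, ignore_index=True) for g, ts in tables.items() if any(len(t) for t in ts)}
    report = group_comparison_report(pooled, summaries, control=control)
    return results, report
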