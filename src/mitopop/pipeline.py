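"""End-to-end glue: simulate -> segment -> quantify -> subpop -> cohort."""

from __future__ import annotations

import pandas as pd

from . import quantify, segment, simulate, subpop
from .cohort import CohortReport, cohort_report
from .segment import SegmentationConfig
from .simulate import CohortSpec, SceneSpec, SubjectSpec


def process_tile(tile, seg_config: SegmentationConfig = SegmentationConfig(),
                 with_granularity: bool = True) -> list:
    """Segment one tile and measure its retained singlets."""
    mask = segment.pixel_classify(tile.trans, seg_config)
    objects = segment.classify_objects(mask, seg_config)
    retained = segment.filter_singlets(objects, seg_config)
    return quantify.measure_cells(tile, retained, with_granularity=with_granularity)


def run_subject(scene: SceneSpec, subject: SubjectSpec,
                seg_config: SegmentationConfig = SegmentationConfig(),
                with_granularity: bool = True) -> pd.DataFrame:
    """Render and measure a subject's full tile set."""
    records = []
    for t in range(subject.n_tiles):
        tile, _ = simulate.render_tile(scene, subject, t)
        records.extend(process_tile(tile, seg_config, with_granularity))
    return quantify.records_to_frame(records)


def run_cohort(cohort: CohortSpec, scene: SceneSpec = SceneSpec(),
               n_tiles: int | None = None,
               seg_config: SegmentationConfig = SegmentationConfig(),
               with_granularity: bool = False,
               min_cells: int = subpop.MIN_CELLS,
               ) -> tuple[pd.DataFrame, pd.DataFrame, CohortReport]:
    """Full pipeline over a planted cohort.

    Returns (cells table, per-subject subpopulation table, cohort report).
    ``n_tiles`` overrides the per-subject tile count for desk-scale runs.
    """
    subjects, covariates = simulate.generate_cohort(cohort)
    if n_tiles is not None:
        subjects = [simulate.scale_down(s, n_tiles) for s in subjects]
    frames = [run_subject(scene, s, seg_config, with_granularity)
              for s in subjects]
    cells = pd.concat(frames, ignore_index=True)
    per_subject = subpop.subpop_pipeline(cells, min_cells=min_cells)
    merged = covariates.merge(per_subject[["patient_id", "prop_low"]],
                              on="patient_id", how="inner")
    report = cohort_report(merged)
    return cells, per_subject, report
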