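"""MS-lesion slice classification from FLAIR-like brain MRI.

Pipeline: labeled 224x224x3 slices -> 1000-dim deep features + 491-dim
hand-crafted features (uniform LBP at radii 1-4, PHOG at 17/34 bins) ->
Brownian-walk firefly selection to 618 + 224 features -> serial fusion
(842 features) -> binary classifiers with stratified five-fold
cross-validation and a percent-scale metric suite (AC/PR/SE/SP/FS).
"""

from importlib import resources

import pandas as pd

from .bfa import (
    BFAConfig,
    SelectionResult,
    brute_force_select,
    cartesian_distance,
    select_features,
    subset_fitness,
)
from .classify import (
    CLASSIFIERS,
    ConfusionCounts,
    CVResult,
    MetricsReport,
    compute_metrics,
    five_fold_cv,
    report_tables,
    roc_curve_points,
    serial_fuse,
    train_classifier,
)
from .deep_features import BackboneSpec, DeepFeatureBlock, extract_deep, test_projection_backbone
from .handcrafted import (
    HCF_DIM,
    HCFBlock,
    LBPConfig,
    PHOGConfig,
    extract_hcf,
    extract_hcf_block,
    lbp_block,
    lbp_histogram,
    phog_descriptor,
)
from .image_io import (
    extract_axial_slices,
    load_manifest,
    load_slice,
    resize_to_standard,
    save_slice,
    split_dataset,
)
from .phantom import PhantomConfig, SliceImage, generate_dataset, generate_phantom, generate_slices
from .pipeline import PipelineConfig, run_pipeline

__version__ = "0.1.0"


def benchmark_reports() -> pd.DataFrame:
    """Published benchmark confusion counts and metric cells bundled for validation.

    Each row holds the TP/FN/TN/FP of one backbone-or-classifier evaluation on
    the MSL benchmark together with its reported AC/PR/SE/SP/FS; feeding the
    counts through :func:`compute_metrics` must reproduce every metric cell.
    """
    with resources.files("mslesion.data").joinpath("benchmark_reports.csv").open() as fh:
        return pd.read_csv(fh)


__all__ = [name for name in dir() if not name.startswith("_")]
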