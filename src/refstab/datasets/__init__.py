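"""Bundled summary datasets from a published Goji (Lycium barbarum)
reference-gene study: per-gene RNA-Seq abundance summaries (mean raw
fragments, SD, CV over 14 samples) and qPCR summaries (amplification
efficiency %, R^2, mean Ct, SD, CV). These are printed summary
statistics; the per-sample raw data are not distributed here."""

from importlib import resources

import pandas as pd

__all__ = ["load_goji_rnaseq_summary", "load_goji_qpcr_summary"]


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_goji_rnaseq_summary() -> pd.DataFrame:
    """Per-transcript mean/SD/CV of raw fragments; 18 candidates + 1 target.

    ``is_candidate`` is 0 for the target gene (LbMYB1), which is not a
    reference-gene candidate.
    """
    return _load("goji_rnaseq_summary.tsv")


def load_goji_qpcr_summary() -> pd.DataFrame:
    """Per-gene qPCR summary: efficiency %, R^2, mean Ct, SD, CV."""
    return _load("goji_qpcr_summary.tsv")
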