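"""Exposure-processing chain: detection-frequency retention, censored
lognormal fill-in imputation, log2 transform, and the Sigma-5-PFAS sum.

Analytes detected in at least 70% of samples are retained (boundary
inclusive); the rest are dropped with a log of name and frequency.  The
composite total-PFAS exposure is the sum of the retained analytes on the
ORIGINAL concentration scale (after imputation), log2-transformed only when
it enters a model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .censored import (
    CensoredLognormalParams,
    fill_in_impute,
    fit_censored_lognormal,
)

__all__ = ["ExposurePanel", "filter_by_detection", "log2_transform", "sum_pfas"]

logger = logging.getLogger(__name__)

DETECTION_THRESHOLD = 0.70
_TOL = 1e-9  # guards float noise at the retention boundary


@dataclass
class ExposurePanel:
    """Per-analyte concentrations with LOD metadata and imputation provenance.

    ``concentrations`` holds raw values with non-detects masked (NaN) before
    imputation and filled-in values afterwards.  ``lod`` maps analyte ->
    scalar or per-record array (per-cycle LODs).
    """

    concentrations: pd.DataFrame
    lod: dict
    nondetect: pd.DataFrame
    params: dict = field(default_factory=dict)
    imputed: bool = False
    seed: int | None = None

    def __post_init__(self):
        if list(self.concentrations.columns) != list(self.nondetect.columns):
            raise ValueError("concentration and non-detect columns must align")

    @property
    def analytes(self) -> list[str]:
        return list(self.concentrations.columns)

    def detection_frequency(self) -> pd.Series:
        return 1.0 - self.nondetect.mean(axis=0)

    # -- processing steps ------------------------------------------------

    def fit_and_impute(self, seed: int = 0) -> "ExposurePanel":
        """Censored-MLE fit then single fill-in imputation per analyte.

        One global seed with per-analyte substreams: analyte k always sees
        the same stream regardless of which other analytes are present.
        """
        streams = {
            a: s
            for a, s in zip(
                self.analytes,
                np.random.SeedSequence(seed).spawn(len(self.analytes)),
            )
        }
        conc = self.concentrations.copy()
        params = {}
        for a in self.analytes:
            flags = self.nondetect[a].to_numpy(dtype=bool)
            p = fit_censored_lognormal(
                conc[a].to_numpy(dtype=float), flags, self.lod[a]
            )
            params[a] = p
            conc[a] = fill_in_impute(
                conc[a].to_numpy(dtype=float),
                flags,
                self.lod[a],
                p,
                rng=np.random.default_rng(streams[a]),
            )
        return ExposurePanel(conc, dict(self.lod), self.nondetect.copy(), params, True, seed)

    def metadata(self) -> dict:
        """Imputation provenance for the sidecar file."""
        freq = self.detection_frequency()
        meta = {"seed": self.seed, "imputed": self.imputed, "analytes": {}}
        for a in self.analytes:
            lod = self.lod[a]
            entry = {
                "lod": float(np.atleast_1d(lod)[0]) if np.ndim(lod) == 0 else "per-record",
                "detection_frequency": float(freq[a]),
            }
            if a in self.params:
                p = self.params[a]
                entry.update(
                    log_mean=p.log_mean,
                    log_sd=p.log_sd,
                    converged=p.converged,
                    n_censored=p.n_censored,
                )
            meta["analytes"][a] = entry
        return meta

    def write_csv(self, path, metadata_path=None):
        self.concentrations.to_csv(path, index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata(), fh, indent=2)


def filter_by_detection(
    panel: ExposurePanel, threshold: float = DETECTION_THRESHOLD
) -> ExposurePanel:
    """Drop analytes detected in fewer than ``threshold`` of samples.

    The boundary is inclusive: an analyte at exactly the threshold is
    retained ("at least 70%").
    """
    freq = panel.detection_frequency()
    keep = [a for a in panel.analytes if freq[a] >= threshold - _TOL]
    dropped = [a for a in panel.analytes if a not in keep]
    for a in dropped:
        logger.info(
            "dropping %s: detection frequency %.1f%% < %.1f%%",
            a,
            100 * freq[a],
            100 * threshold,
        )
    if not keep:
        raise ValueError("no analytes survive the detection-frequency filter")
    return ExposurePanel(
        panel.concentrations[keep].copy(),
        {a: panel.lod[a] for a in keep},
        panel.nondetect[keep].copy(),
        {a: p for a, p in panel.params.items() if a in keep},
        panel.imputed,
        panel.seed,
    )


def _require_positive(values: pd.DataFrame | pd.Series | np.ndarray):
    arr = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError(
            "nonpositive or missing concentration reached the transform; "
            "imputation contract violated"
        )


def log2_transform(values):
    """log2 of concentrations; errors on nonpositive values."""
    _require_positive(values)
    if isinstance(values, (pd.DataFrame, pd.Series)):
        return np.log2(values)
    return np.log2(np.asarray(values, dtype=float))


def sum_pfas(panel: ExposurePanel | pd.DataFrame) -> pd.Series:
    """Sigma-PFAS: per-participant sum on the original concentration scale.

    Imputation must be complete (sub-LOD members enter via their imputed
    values).  log2 is applied separately when the sum enters a model.
    """
    conc = panel.concentrations if isinstance(panel, ExposurePanel) else panel
    if isinstance(panel, ExposurePanel) and panel.nondetect.to_numpy().any() and not panel.imputed:
        raise ValueError("impute non-detects before summing concentrations")
    _require_positive(conc)
    return conc.sum(axis=1)
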