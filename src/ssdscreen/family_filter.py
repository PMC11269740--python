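"""Inclusion filters for the gene-family count matrix.

Three rules decide whether a family enters the regression screen:

* prevalence — present (count > 0) in at least ceil(threshold * n_species)
  species, removing lineage-specific families;
* max count — at least ``min_max_count`` genes in at least one species,
  avoiding pure presence/absence comparisons;
* variance — some variation in gene number across species, since a regression
  cannot explain variance that is not there.

Every input family gets a report row recording which rules it failed.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)


def filter_families(
    counts: pd.DataFrame, config: AnalysisConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three inclusion rules to a families x species count matrix.

    Parameters
    ----------
    counts : DataFrame
        Integer counts, indexed by family id, one column per species.
    config : AnalysisConfig
        Supplies ``prevalence_threshold`` and ``min_max_count``.

    Returns
    -------
    (filtered, report)
        ``filtered`` retains exactly the passing families (same column order);
        ``report`` has one row per input family with columns ``family``,
        ``prevalence``, ``max_count``, ``variance``, ``passed``,
        ``failed_rules`` (comma-joined subset of prevalence/max_count/variance).
    """
    if config is None:
        config = AnalysisConfig()
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise ValidationError("count matrix is empty")
    arr = counts.to_numpy()
    if np.any(arr < 0):
        raise ValidationError("count matrix contains negative values")
    n_species = counts.shape[1]
    need = math.ceil(config.prevalence_threshold * n_species)

    present = (arr > 0).sum(axis=1)
    prevalence = present / n_species
    max_count = arr.max(axis=1)
    variance = arr.var(axis=1, ddof=0).astype(float)

    fail_prev = present < need
    fail_max = max_count < config.min_max_count
    fail_var = variance == 0

    failed = []
    for fp, fm, fv in zip(fail_prev, fail_max, fail_var):
        rules = [name for flag, name in
                 ((fp, "prevalence"), (fm, "max_count"), (fv, "variance")) if flag]
        failed.append(",".join(rules))
    passed = ~(fail_prev | fail_max | fail_var)

    report = pd.DataFrame({
        "family": counts.index,
        "prevalence": prevalence,
        "max_count": max_count,
        "variance": variance,
        "passed": passed,
        "failed_rules": failed,
    })
    filtered = counts.loc[passed]
    logger.info(
        "family filter: %d/%d retained (need presence in >= %d of %d species; "
        "max count >= %d; variance > 0)",
        len(filtered), len(counts), need, n_species, config.min_max_count,
    )
    if len(filtered) == 0:
        warnings.warn("family filter retained no families", stacklevel=2)
    return filtered, report
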