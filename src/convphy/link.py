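"""Locus-wise regressions of convergence support on selection pressure.

Per-site dSSLS (convergence support) is joined with the per-site
posterior-mean omega from M8 (only for loci where the M8 model was
favored) and with the Clade Model C site category; within each (locus,
category) group an ordinary least squares fit dSSLS ~ omega classifies
the locus as having a positive, negative or non-significant coupling
between sitewise selection and convergence support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm


def join_site_metrics(ssls: pd.DataFrame, m8: pd.DataFrame,
                      cmc: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the three per-site tables on (gene, site).

    Expected columns: ssls (gene, site, dssls), m8 (gene, site, omega),
    cmc (gene, site, category).  Sites missing any metric are dropped;
    the drop counts are recorded in ``DataFrame.attrs['dropped']``.
    """
    for name, df, cols in (("ssls", ssls, {"gene", "site", "dssls"}),
                           ("m8", m8, {"gene", "site", "omega"}),
                           ("cmc", cmc, {"gene", "site", "category"})):
        missing = cols - set(df.columns)
        if missing:
            raise ValueError(f"{name} table lacks columns {sorted(missing)}")
        if df.duplicated(["gene", "site"]).any():
            raise ValueError(f"duplicate (gene, site) keys in {name} table")
    joined = (ssls.merge(m8, on=["gene", "site"], how="inner")
                  .merge(cmc, on=["gene", "site"], how="inner"))
    joined.attrs["dropped"] = {
        "ssls_only": int(len(ssls) - len(joined)),
        "m8_only": int(len(m8) - len(joined)),
        "cmc_only": int(len(cmc) - len(joined)),
    }
    return joined


@dataclass
class LocusRegression:
    gene: str
    category: int
    slope: float
    intercept: float
    p_value: float
    n_sites: int
    classification: str  # positive | negative | ns


def fit_locus_regressions(
    join_table: pd.DataFrame,
    min_sites: int = 10,
    alpha: float = 0.05,
    per_category: bool = True,
) -> tuple[list[LocusRegression], pd.DataFrame]:
    """OLS of dSSLS on omega per (gene, category) group.

    Groups with fewer than ``min_sites`` sites or zero omega variance
    are skipped.  The cohort summary reports, per category, the
    fraction of significant loci with positive vs negative slope.
    """
    keys = ["gene", "category"] if per_category else ["gene"]
    results: list[LocusRegression] = []
    for key, grp in join_table.groupby(keys, sort=True):
        gene, category = key if per_category else (key[0], -1)
        if len(grp) < min_sites:
            continue
        omega = grp["omega"].to_numpy(dtype=float)
        y = grp["dssls"].to_numpy(dtype=float)
        if np.ptp(omega) <= 0:
            continue  # zero variance in the covariate
        fit = sm.OLS(y, sm.add_constant(omega)).fit()
        slope = float(fit.params[1])
        p = float(fit.pvalues[1])
        if p <= alpha:
            cls = "positive" if slope > 0 else "negative"
        else:
            cls = "ns"
        results.append(LocusRegression(
            gene=gene, category=int(category), slope=slope,
            intercept=float(fit.params[0]), p_value=p,
            n_sites=len(grp), classification=cls))

    rows = []
    frame = pd.DataFrame([r.__dict__ for r in results])
    if not frame.empty:
        for category, grp in frame.groupby("category", sort=True):
            n = len(grp)
            counts = grp["classification"].value_counts()
            n_sig = int((grp["classification"] != "ns").sum())
            rows.append({
                "category": int(category),
                "n_loci": n,
                "frac_positive": counts.get("positive", 0) / n,
                "frac_negative": counts.get("negative", 0) / n,
                "frac_ns": counts.get("ns", 0) / n,
                "n_significant": n_sig,
                "frac_positive_of_significant":
                    (counts.get("positive", 0) / n_sig) if n_sig else np.nan,
            })
    return results, pd.DataFrame(rows)


def regressions_to_frame(results: list[LocusRegression]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
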