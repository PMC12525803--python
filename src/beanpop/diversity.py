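"""Per-population diversity and inbreeding summaries.

For each population and each locus with at least one called genotype:

* ``Ho`` — observed heterozygosity, heterozygotes / called genotypes;
* ``He`` — expected heterozygosity ``1 − p² − q²`` from the
  population's allele frequencies at that locus;
* ``uHe`` — the small-sample unbiased expectation
  ``He · 2n/(2n − 1)`` with ``n`` the called genotypes at that locus;
* ``FIS = 1 − mean(Ho)/mean(uHe)`` over the assessed loci.

Population values are unweighted means over assessed loci.  Loci with
no called genotype in a population are excluded from that population's
means (not zero-filled), and ``n`` is the per-locus called count, not
the population census.  Polymorphic/monomorphic locus counts refer to
the alleles actually observed within the population.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dart_io import SNPDataset

REPORT_COLUMNS = ["poly_loc", "mono_loc", "ho", "he", "uhe", "fis"]


def diversity_report(ds: SNPDataset, polymorphic_only: bool = False) -> pd.DataFrame:
    """One row per population with poly/mono locus counts, Ho, He, uHe, FIS.

    ``polymorphic_only`` restricts the means to loci that are polymorphic
    somewhere in the whole dataset (the poly/mono counts always refer to
    the loci assessed).
    """
    if not ds.populations:
        raise ValueError("dataset has no populations")

    loci_mask = np.ones(ds.n_loci, dtype=bool)
    if polymorphic_only:
        g = ds.genotypes
        has_ref = ((g == 0) | (g == 1)).any(axis=0)
        has_alt = ((g == 2) | (g == 1)).any(axis=0)
        loci_mask = has_ref & has_alt

    rows = {}
    for pop in ds.populations:
        g = ds.genotypes[ds.population_indices(pop)][:, loci_mask]
        n0 = (g == 0).sum(axis=0).astype(float)
        n1 = (g == 1).sum(axis=0).astype(float)
        n2 = (g == 2).sum(axis=0).astype(float)
        n = n0 + n1 + n2
        assessed = n >= 1
        if not assessed.any():
            rows[pop] = dict.fromkeys(REPORT_COLUMNS, np.nan)
            continue
        n0, n1, n2, n = (x[assessed] for x in (n0, n1, n2, n))
        p = (2 * n0 + n1) / (2 * n)
        ho = n1 / n
        he = 1.0 - p**2 - (1.0 - p) ** 2
        uhe = he * (2 * n) / (2 * n - 1)
        poly = (p > 0) & (p < 1)
        mean_ho, mean_uhe = float(ho.mean()), float(uhe.mean())
        rows[pop] = {
            "poly_loc": int(poly.sum()),
            "mono_loc": int((~poly).sum()),
            "ho": mean_ho,
            "he": float(he.mean()),
            "uhe": mean_uhe,
            "fis": 1.0 - mean_ho / mean_uhe if mean_uhe > 0 else np.nan,
        }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=REPORT_COLUMNS)
    df.index.name = "population"
    return df
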