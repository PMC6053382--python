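"""ddCT relative quantification with dual endogenous controls.

Replicate CTs are averaged per sample; dCT subtracts the arithmetic mean of
the housekeeping CTs (GAPDH, HPRT1 -- the arithmetic mean of CTs is the
geometric mean of expression); ddCT references the calibrator group's mean
dCT; RQ = 2^(-ddCT) with amplification efficiency fixed at 2. Down-regulated
genes are displayed with the signed-fold convention ``-1/RQ``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import HOUSEKEEPING_GENES, QpcrResult, QpcrSample, signed_fold

__all__ = ["mean_ct", "delta_ct", "relative_quantity", "qpcr_pipeline",
           "results_to_frame"]

REPLICATE_RANGE_WARN = 0.5  # cycles


def mean_ct(sample: QpcrSample) -> tuple[float, float]:
    """Mean and SD of the finite replicate CTs; warns when the replicate
    range exceeds 0.5 cycles."""
    ct = sample.ct_values[np.isfinite(sample.ct_values)]
    rng = float(ct.max() - ct.min()) if ct.size > 1 else 0.0
    if rng > REPLICATE_RANGE_WARN:
        warnings.warn(
            f"sample {sample.sample_id} gene {sample.gene}: replicate range "
            f"{rng:.2f} cycles exceeds {REPLICATE_RANGE_WARN}")
    sd = float(np.std(ct, ddof=1)) if ct.size > 1 else float("nan")
    return float(ct.mean()), sd


def delta_ct(target_ct: float, ref_cts: dict) -> float:
    """dCT = target CT - mean CT over the available housekeeping genes."""
    refs = [v for v in ref_cts.values() if np.isfinite(v)]
    if not refs:
        raise ValueError("no finite reference-gene CT available")
    return float(target_ct - np.mean(refs))


def relative_quantity(dct_sample: float, dct_calibrator: float,
                      gene: str = "", group: str = "") -> QpcrResult:
    """Single ddCT evaluation: RQ = 2^(-(dCT_sample - dCT_calibrator))."""
    if not (np.isfinite(dct_sample) and np.isfinite(dct_calibrator)):
        raise ValueError("dCT values must be finite")
    ddct = dct_sample - dct_calibrator
    rq = 2.0 ** (-ddct)
    return QpcrResult(gene=gene, group=group, delta_ct=dct_sample,
                      delta_delta_ct=ddct, rq=rq, signed_fold=signed_fold(rq))


def _sample_dcts(samples, reference_genes) -> pd.DataFrame:
    """Per (group, sample, target gene) dCT table."""
    rows = []
    by_sample: dict[tuple, dict] = {}
    for s in samples:
        by_sample.setdefault((s.group, s.sample_id), {})[s.gene] = s
    for (group, sid), genes in sorted(by_sample.items()):
        refs = {g: mean_ct(genes[g])[0] for g in reference_genes if g in genes}
        if not refs:
            raise ValueError(f"sample {sid}: no housekeeping gene present")
        for gene, s in sorted(genes.items()):
            if gene in reference_genes:
                continue
            rows.append({"group": group, "sample_id": sid, "gene": gene,
                         "dct": delta_ct(mean_ct(s)[0], refs)})
    return pd.DataFrame(rows)


def qpcr_pipeline(samples, calibrator_group: str,
                  reference_genes=HOUSEKEEPING_GENES) -> list[QpcrResult]:
    """Full ddCT pipeline over a CT table.

    Per gene x group: sample dCTs (target minus mean housekeeping CT), group
    mean dCT, ddCT against the calibrator group's mean dCT, RQ and signed
    fold. The SEM is that of the per-sample signed folds, matching the
    "RQ +/- SEM" display. The calibrator group's own signed fold is exactly
    +1 by construction.
    """
    table = _sample_dcts(samples, reference_genes)
    if calibrator_group not in set(table["group"]):
        raise ValueError(f"calibrator group {calibrator_group!r} absent from table")
    results = []
    for gene, sub in table.groupby("gene", sort=True):
        cal = sub[sub["group"] == calibrator_group]["dct"]
        if cal.empty:
            raise ValueError(f"gene {gene}: missing from calibrator group "
                             f"{calibrator_group!r}")
        dct_cal = float(cal.mean())
        for group, gsub in sub.groupby("group", sort=True):
            dct_group = float(gsub["dct"].mean())
            ddct = dct_group - dct_cal
            rq = 2.0 ** (-ddct)
            per_sample_folds = np.array(
                [signed_fold(2.0 ** (-(d - dct_cal))) for d in gsub["dct"]])
            n = per_sample_folds.size
            sem = (float(np.std(per_sample_folds, ddof=1) / np.sqrt(n))
                   if n > 1 else float("nan"))
            results.append(QpcrResult(
                gene=gene, group=group, delta_ct=dct_group,
                delta_delta_ct=ddct, rq=rq, signed_fold=signed_fold(rq),
                sem=sem, n_samples=n))
    return results


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene": r.gene, "group": r.group, "dct": r.delta_ct,
        "ddct": r.delta_delta_ct, "rq": r.rq, "signed_fold": r.signed_fold,
        "sem": r.sem, "n_samples": r.n_samples,
    } for r in results])
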