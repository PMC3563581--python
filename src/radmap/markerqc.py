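"""Marker QC cascade: cross typing, inheritance errors, distortion, missingness.

Outbred full-sib cross types: B3 (AB x AB, offspring 1:2:1), D1 (AB x hom,
1:1, informative for the female meiosis only), D2 (hom x AB, male only).
The fixed cascade is

1. markers with a missing parent call are removed;
2. offspring calls impossible under Mendelian transmission are set missing,
   and markers with an excess of such errors are removed;
3. markers whose cleaned offspring counts deviate from the expected 1:1 or
   1:2:1 ratio (chi-square, p < alpha) are removed — in salmonids most of
   these are collapsed paralogs that present as universal heterozygotes;
4. markers with more than ``max_missing`` missing offspring calls are removed.

Rerunning the cascade on its own output changes nothing (idempotence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .genotype import MISSING, CALL_CODES, GenotypeMatrix

CROSS_B3 = "B3"
CROSS_D1 = "D1"
CROSS_D2 = "D2"
CROSS_UNINFORMATIVE = "uninformative"
CROSS_PARENT_MISSING = "parent_missing"

FLAG_PARENT_MISSING = "parent_missing"
FLAG_INHERITANCE = "inheritance_excess"
FLAG_DISTORTED = "distorted"
FLAG_MISSING = "missing_excess"

# allowed[mother, father, offspring] under Mendelian transmission
_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
ALLOWED = np.zeros((3, 3, 3), dtype=bool)
for _m, _ma in _ALLELES.items():
    for _f, _fa in _ALLELES.items():
        for _x in _ma:
            for _y in _fa:
                ALLOWED[_m, _f, _x + _y] = True


def _as_code(call) -> int:
    if isinstance(call, str):
        return CALL_CODES[call]
    return int(call)


def classify_cross_type(mother_call, father_call) -> str:
    """Cross type from the two parental calls (codes or 'AA'/'AB'/'BB'/'--')."""
    m, f = _as_code(mother_call), _as_code(father_call)
    if m == MISSING or f == MISSING:
        return CROSS_PARENT_MISSING
    if m == 1 and f == 1:
        return CROSS_B3
    if m == 1:
        return CROSS_D1
    if f == 1:
        return CROSS_D2
    return CROSS_UNINFORMATIVE


def classify_all(gm: GenotypeMatrix) -> pd.Series:
    m, f = gm.mother, gm.father
    out = np.full(gm.n_loci, CROSS_UNINFORMATIVE, dtype=object)
    out[(m == 1) & (f == 1)] = CROSS_B3
    out[(m == 1) & (f != 1) & (f != MISSING)] = CROSS_D1
    out[(f == 1) & (m != 1) & (m != MISSING)] = CROSS_D2
    out[(m == MISSING) | (f == MISSING)] = CROSS_PARENT_MISSING
    return pd.Series(out, index=gm.loci, name="cross_type")


def inheritance_screen(offspring_calls: np.ndarray, mother_call, father_call,
                       max_error_fraction: float = 0.10):
    """Convert Mendelian-impossible calls to missing; flag excess errors.

    Returns ``(cleaned_calls, n_errors, flagged)``; the error fraction is
    taken over offspring with a call.
    """
    m, f = _as_code(mother_call), _as_code(father_call)
    calls = np.asarray(offspring_calls, dtype=np.int8).copy()
    present = calls != MISSING
    if m == MISSING or f == MISSING:
        return calls, 0, False
    bad = present & ~ALLOWED[m, f, np.clip(calls, 0, 2)]
    calls[bad] = MISSING
    n_present = int(present.sum())
    n_err = int(bad.sum())
    flagged = n_present > 0 and n_err / n_present > max_error_fraction
    return calls, n_err, flagged


def distortion_test(offspring_calls: np.ndarray, cross_type: str,
                    alpha: float = 0.05):
    """Chi-square test of 1:1 (D1/D2) or 1:2:1 (B3) segregation.

    Missing calls are excluded; no continuity correction (family sizes of
    ~96 make the asymptotic test adequate).  Returns
    ``(chi2, df, p, keep)``; a marker with no scored offspring is removed.
    """
    calls = np.asarray(offspring_calls)
    calls = calls[calls != MISSING]
    n = calls.size
    if n == 0:
        return np.nan, 0, np.nan, False
    if cross_type == CROSS_B3:
        observed = np.array([(calls == g).sum() for g in (0, 1, 2)], dtype=float)
        expected = np.array([n / 4, n / 2, n / 4])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        df = 2
    elif cross_type in (CROSS_D1, CROSS_D2):
        het = int((calls == 1).sum())
        chi2 = float((het - (n - het)) ** 2 / n)
        df = 1
    else:
        raise ValueError(f"distortion test undefined for cross type {cross_type!r}")
    p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p, p >= alpha


def missingness_filter(offspring_calls: np.ndarray,
                       max_missing_fraction: float = 0.25) -> bool:
    """Keep iff the missing fraction does not exceed the threshold (strict >)."""
    calls = np.asarray(offspring_calls)
    frac = float((calls == MISSING).mean())
    return frac <= max_missing_fraction


@dataclass
class QCResult:
    """QC cascade output: per-marker report plus the filtered, cleaned matrix."""

    report: pd.DataFrame
    cleaned: GenotypeMatrix     # all input loci, impossible calls set missing
    filtered: GenotypeMatrix    # kept loci only
    cross_types: pd.Series      # for kept loci

    @property
    def kept_loci(self) -> pd.Index:
        return self.filtered.loci

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        self.filtered.to_tsv(outdir / "genotypes_qc.tsv")


def run_qc(gm: GenotypeMatrix, max_error_fraction: float = 0.10,
           alpha: float = 0.05, max_missing: float = 0.25) -> QCResult:
    """Apply the full cascade in fixed order to every marker."""
    cross = classify_all(gm)
    cleaned = gm.copy()
    rows = []
    keep_mask = np.zeros(gm.n_loci, dtype=bool)

    for i, locus in enumerate(gm.loci):
        ct = cross.iloc[i]
        flags = []
        chi2 = df = p = np.nan
        n_err = 0
        if ct == CROSS_PARENT_MISSING:
            flags.append(FLAG_PARENT_MISSING)
            decision = "remove"
            missing_frac = float((gm.calls[i] == MISSING).mean())
        else:
            calls, n_err, flagged = inheritance_screen(
                gm.calls[i], gm.mother[i], gm.father[i], max_error_fraction
            )
            cleaned.calls[i] = calls
            missing_frac = float((calls == MISSING).mean())
            decision = "keep"
            if flagged:
                flags.append(FLAG_INHERITANCE)
                decision = "remove"
            elif ct in (CROSS_B3, CROSS_D1, CROSS_D2):
                n_scored = int((calls != MISSING).sum())
                if n_scored == 0:
                    flags.append(FLAG_MISSING)
                    decision = "remove"
                else:
                    chi2, df, p, ok = distortion_test(calls, ct, alpha)
                    if not ok:
                        flags.append(FLAG_DISTORTED)
                        decision = "remove"
            if decision == "keep" and not missingness_filter(calls, max_missing):
                flags.append(FLAG_MISSING)
                decision = "remove"
        keep_mask[i] = decision == "keep"
        rows.append(
            {
                "locus_id": locus,
                "cross_type": ct,
                "n_inheritance_errors": n_err,
                "chi2": chi2,
                "df": df,
                "p": p,
                "missing_fraction": missing_frac,
                "flags": ";".join(flags),
                "decision": decision,
            }
        )

    report = pd.DataFrame.from_records(rows)
    filtered = cleaned.subset(keep_mask)
    return QCResult(
        report=report,
        cleaned=cleaned,
        filtered=filtered,
        cross_types=cross[keep_mask],
    )


def write_outcross(gm: GenotypeMatrix, cross_types: pd.Series, path) -> int:
    """Write kept informative markers in CP-style outcross coding.

    B3 -> <hkxhk> (hh/hk/kk), D1 -> <lmxll> (lm = maternal-B carrier),
    D2 -> <nnxnp>.  Interoperable with outcross mapping tools that accept
    JoinMap-style CP locus codes.
    """
    code_maps = {
        CROSS_B3: {0: "hh", 1: "hk", 2: "kk", MISSING: "--"},
        CROSS_D1: None,  # built per marker (depends on which hom class exists)
        CROSS_D2: None,
    }
    seg = {CROSS_B3: "<hkxhk>", CROSS_D1: "<lmxll>", CROSS_D2: "<nnxnp>"}
    n_written = 0
    with open(path, "w") as fh:
        informative = [
            i for i, locus in enumerate(gm.loci)
            if cross_types.loc[locus] in seg
        ]
        fh.write(f"{gm.n_offspring} {len(informative)}\n")
        for i in informative:
            ct = cross_types.loc[gm.loci[i]]
            if ct == CROSS_B3:
                mapping = code_maps[CROSS_B3]
            else:
                hom_codes = ("ll", "lm") if ct == CROSS_D1 else ("nn", "np")
                mapping = {1: hom_codes[1], MISSING: "--"}
                for g in (0, 2):
                    mapping[g] = hom_codes[0]
            coded = " ".join(mapping[int(c)] for c in gm.calls[i])
            fh.write(f"*{gm.loci[i]} {seg[ct]} {coded}\n")
            n_written += 1
    return n_written
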