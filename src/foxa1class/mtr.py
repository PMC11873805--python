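"""Per-residue missense tolerance ratio (MTR) profiling.

The MTR compares, within a sliding codon window centred on each residue,
the observed fraction of missense (vs synonymous) variants to the
fraction expected if every possible single-nucleotide change were equally
likely:

    MTR = (obs_mis / (obs_mis + obs_syn)) / (poss_mis / (poss_mis + poss_syn))

MTR = 1 is neutrality; values well below 1 mark residues intolerant of
missense variation.  Possible-consequence counts come from exhaustive
enumeration of the 9 single-nucleotide changes of each codon under the
standard genetic code; nonsense changes are excluded from both numerator
and denominator.  Departures from the expected fraction are assessed per
residue with a two-sided exact binomial test (minimum-likelihood method)
and BH-adjusted across residues.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_WINDOW = 31  # codons; the sliding-window convention for MTR scans

_NUCS = "ACGT"


def enumerate_codon_consequences(cds: str) -> pd.DataFrame:
    """Classify all 9 SNVs of every codon of a coding sequence.

    Returns one row per residue (1-based) with columns ``codon``,
    ``aa``, ``possible_missense``, ``possible_synonymous``,
    ``possible_nonsense``; the three counts sum to 9 for every codon
    encoding an amino acid.  A terminal stop codon is dropped.  Length
    not divisible by 3 or invalid characters raise a format error; a CDS
    not starting with ATG only warns.
    """
    seq = cds.strip().upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not a multiple of 3")
    if not seq or set(seq) - set(_NUCS):
        bad = sorted(set(seq) - set(_NUCS))
        raise ValueError(f"invalid nucleotide(s) in CDS: {bad}")
    if not seq.startswith("ATG"):
        warnings.warn("CDS does not start with ATG", stacklevel=2)
    rows = []
    residue = 0
    n_codons = len(seq) // 3
    for i in range(n_codons):
        codon = seq[3 * i : 3 * i + 3]
        aa = str(Seq(codon).translate())
        if aa == "*":
            if i != n_codons - 1:
                warnings.warn(f"internal stop codon at codon {i + 1}", stacklevel=2)
            continue
        residue += 1
        mis = syn = non = 0
        for pos in range(3):
            for nuc in _NUCS:
                if nuc == codon[pos]:
                    continue
                alt = str(Seq(codon[:pos] + nuc + codon[pos + 1 :]).translate())
                if alt == "*":
                    non += 1
                elif alt == aa:
                    syn += 1
                else:
                    mis += 1
        rows.append((residue, codon, aa, mis, syn, non))
    return pd.DataFrame(
        rows,
        columns=[
            "residue", "codon", "aa",
            "possible_missense", "possible_synonymous", "possible_nonsense",
        ],
    )


def _window_sum(x: np.ndarray, window: int) -> np.ndarray:
    """Centred sliding-window sums, truncated at the termini."""
    n = len(x)
    half = window // 2
    cs = np.concatenate([[0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return cs[hi] - cs[lo]


def compute_mtr(
    observed: pd.DataFrame,
    table: pd.DataFrame,
    window: int = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """Sliding-window MTR profile over all residues of the gene.

    ``observed`` holds one row per observed variant with columns
    ``residue`` (1-based) and ``consequence`` in {missense, synonymous};
    ``table`` is the output of :func:`enumerate_codon_consequences`.
    The window is centred and truncated at the termini; MTR is missing
    for windows with no observed variants.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be a positive odd codon count, got {window}")
    bad = set(observed["consequence"]) - {"missense", "synonymous"}
    if bad:
        raise ValueError(f"unsupported consequence(s): {sorted(bad)}")
    residues = table["residue"].to_numpy()
    n = len(residues)
    obs_mis = np.zeros(n)
    obs_syn = np.zeros(n)
    idx = {r: i for i, r in enumerate(residues)}
    for r, cons in zip(observed["residue"], observed["consequence"]):
        if r not in idx:
            raise ValueError(f"observed variant at residue {r} outside the gene")
        if cons == "missense":
            obs_mis[idx[r]] += 1
        else:
            obs_syn[idx[r]] += 1
    w_obs_mis = _window_sum(obs_mis, window)
    w_obs_syn = _window_sum(obs_syn, window)
    w_pos_mis = _window_sum(table["possible_missense"].to_numpy(float), window)
    w_pos_syn = _window_sum(table["possible_synonymous"].to_numpy(float), window)
    exp_frac = w_pos_mis / (w_pos_mis + w_pos_syn)
    obs_total = w_obs_mis + w_obs_syn
    with np.errstate(invalid="ignore", divide="ignore"):
        obs_frac = np.where(obs_total > 0, w_obs_mis / np.maximum(obs_total, 1), np.nan)
        mtr = obs_frac / exp_frac
    return pd.DataFrame(
        {
            "residue": residues,
            "window_obs_missense": w_obs_mis.astype(int),
            "window_obs_synonymous": w_obs_syn.astype(int),
            "window_exp_missense_fraction": exp_frac,
            "mtr": mtr,
            "window": window,
        }
    )


def residue_binomial_tests(
    profile: pd.DataFrame, *, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Exact binomial p (and BH q) per residue for the MTR profile.

    Tests window_obs_missense successes out of the window's observed
    total against the expected missense fraction.  ``alternative`` may be
    ``"less"`` for a one-sided intolerance scan.  Zero-trial windows get
    missing p and q.
    """
    ps = np.full(len(profile), np.nan)
    for i, (k, s, f) in enumerate(
        zip(
            profile["window_obs_missense"],
            profile["window_obs_synonymous"],
            profile["window_exp_missense_fraction"],
        )
    ):
        n = int(k + s)
        if n == 0:
            continue
        ps[i] = stats.binomtest(int(k), n, float(f), alternative=alternative).pvalue
    out = profile.copy()
    out["p"] = ps
    out["q"] = np.nan
    ok = ~np.isnan(ps)
    if ok.any():
        out.loc[ok, "q"] = multipletests(ps[ok], method="fdr_bh")[1]
    return out


def mtr_percentiles(
    profile: pd.DataFrame, percentiles: Sequence[float] = (5, 25, 50)
) -> dict[float, float]:
    """Gene-specific MTR percentile thresholds over defined-MTR residues."""
    vals = profile["mtr"].dropna().to_numpy()
    if len(vals) == 0:
        return {p: np.nan for p in percentiles}
    return {p: float(np.percentile(vals, p)) for p in percentiles}


def sample_neutral_variants(
    table: pd.DataFrame, n_variants: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw variants proportional to each residue's possible consequences.

    Under this neutral sampler the expected MTR is 1 everywhere; used for
    calibration checks of the profile and its binomial tests.
    """
    weights = (
        table["possible_missense"].to_numpy(float)
        + table["possible_synonymous"].to_numpy(float)
    )
    probs = weights / weights.sum()
    picks = rng.choice(len(table), size=n_variants, p=probs)
    p_mis = table["possible_missense"].to_numpy(float)[picks] / weights[picks]
    is_mis = rng.random(n_variants) < p_mis
    return pd.DataFrame(
        {
            "residue": table["residue"].to_numpy()[picks],
            "consequence": np.where(is_mis, "missense", "synonymous"),
        }
    )
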