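"""Batch drivers for random-network surveys and binarization comparisons.

All drivers are fully reproducible from (configuration, seed).  Sample
sizes default to desk-scale values; the statistics of interest (mean
number of distinctions, Phi distributions, correlations) are stable well
below the thousands of networks per class used for publication figures.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import states as st
from .binarize import faure_kaji, tonello
from .config import DEFAULT_CONFIG, RunConfig
from .exceptions import ValidationError
from .generators import (
    ClassLabel,
    random_asymptotic_function,
    random_deterministic_tpm,
)
from .network import Network, effective_information
from .system import sia

__all__ = [
    "SurveyRecord",
    "sample_state_from_tpm",
    "run_class_survey",
    "run_shared_tpm_comparison",
    "run_binarization_correlation",
    "bootstrap_ci",
]


@dataclasses.dataclass(frozen=True)
class SurveyRecord:
    class_label: str
    sample: int
    state: Tuple[int, ...]
    big_phi: float
    mean_small_phi: Optional[float]
    n_distinctions: int
    effective_information: float


def sample_state_from_tpm(net: Network, rng: np.random.Generator) -> Tuple[int, ...]:
    """One state chosen at random from the system's TPM: draw a row
    uniformly and sample its successor.  The result is reachable by
    construction (it has a positive TPM column)."""
    row = int(rng.integers(net.S))
    col = int(rng.choice(net.S, p=net.tpm[row]))
    return st.decode_state(col, net.radices)


def bootstrap_ci(
    values: Sequence[float],
    rng: np.random.Generator,
    n_boot: int = 1000,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    values = np.asarray(values, dtype=float)
    means = np.empty(n_boot)
    n = len(values)
    for b in range(n_boot):
        means[b] = values[rng.integers(0, n, size=n)].mean()
    alpha = (1 - level) / 2
    return (
        float(np.quantile(means, alpha)),
        float(np.quantile(means, 1 - alpha)),
    )


def _summary(values, name, rng) -> Dict[str, float]:
    values = np.asarray([v for v in values if v is not None], dtype=float)
    if values.size == 0:
        return {f"{name}_n": 0}
    lo, hi = bootstrap_ci(values, rng) if values.size > 1 else (values[0], values[0])
    return {
        f"{name}_mean": float(values.mean()),
        f"{name}_q25": float(np.quantile(values, 0.25)),
        f"{name}_median": float(np.quantile(values, 0.5)),
        f"{name}_q75": float(np.quantile(values, 0.75)),
        f"{name}_ci_low": lo,
        f"{name}_ci_high": hi,
        f"{name}_n": int(values.size),
    }


def run_class_survey(
    label,
    n_samples: int,
    seed,
    config: RunConfig = DEFAULT_CONFIG,
    compute_big_phi: bool = True,
    out_csv=None,
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Survey random deterministic networks of one class.

    For each sampled network, the whole-system CES (and, optionally, Phi)
    is computed for one state chosen at random from its TPM.  Returns the
    per-network records and summary statistics (means, quartiles and
    bootstrap CIs).  Records stream to ``out_csv`` if given, so partial
    runs remain usable.
    """
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    label = ClassLabel.parse(label)
    rng = np.random.default_rng(seed)
    records: List[SurveyRecord] = []
    header_written = False
    for k in range(n_samples):
        tpm = random_deterministic_tpm(label.S, rng)
        net = Network(tpm, label.digits)
        state = sample_state_from_tpm(net, rng)
        if compute_big_phi:
            result = sia(net, state, config)
            ces = result.ces
            big_phi = result.big_phi
        else:
            from .system import compute_ces

            ces = compute_ces(net, state, config)
            big_phi = float("nan")
        rec = SurveyRecord(
            class_label=str(label),
            sample=k,
            state=state,
            big_phi=big_phi,
            mean_small_phi=ces.mean_phi,
            n_distinctions=len(ces),
            effective_information=effective_information(net),
        )
        records.append(rec)
        if out_csv is not None:
            frame = pd.DataFrame([dataclasses.asdict(rec)])
            frame.to_csv(
                out_csv, mode="a" if header_written else "w",
                header=not header_written, index=False,
            )
            header_written = True
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    summary_rng = np.random.default_rng(rng.integers(2**31))
    summary: Dict[str, float] = {"class": str(label), "n_samples": n_samples}
    summary.update(_summary(df["n_distinctions"], "n_distinctions", summary_rng))
    summary.update(_summary(df["mean_small_phi"], "mean_small_phi", summary_rng))
    if compute_big_phi:
        summary.update(_summary(df["big_phi"], "big_phi", summary_rng))
    return df, summary


def run_shared_tpm_comparison(
    pair: Tuple[str, str],
    n: int,
    seed,
    shared: bool = True,
    config: RunConfig = DEFAULT_CONFIG,
) -> Dict[str, object]:
    """Compare Phi across two classes with equal state counts.

    With ``shared=True`` each sample draws one TPM and reads it with both
    classes' radices (e.g. four binary nodes vs two quaternary nodes);
    otherwise the two classes get independent draws.  Reports the Pearson
    correlation of Phi, two-sample KS statistics on Phi and mean small
    phi, and whether effective information matched exactly per pair.
    """
    la, lb = (ClassLabel.parse(p) for p in pair)
    if la.S != lb.S:
        raise ValidationError("paired classes must have the same total state count")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n):
        tpm_a = random_deterministic_tpm(la.S, rng)
        tpm_b = tpm_a if shared else random_deterministic_tpm(lb.S, rng)
        net_a = Network(tpm_a, la.digits)
        net_b = Network(tpm_b, lb.digits)
        state_a = sample_state_from_tpm(net_a, rng)
        if shared:
            # same joint state, re-read with the other radices
            state_b = st.decode_state(st.encode_state(state_a, la.digits), lb.digits)
        else:
            state_b = sample_state_from_tpm(net_b, rng)
        res_a = sia(net_a, state_a, config)
        res_b = sia(net_b, state_b, config)
        rows.append(
            {
                "sample": k,
                "phi_a": res_a.big_phi,
                "phi_b": res_b.big_phi,
                "mean_small_phi_a": res_a.ces.mean_phi,
                "mean_small_phi_b": res_b.ces.mean_phi,
                "ei_a": effective_information(net_a),
                "ei_b": effective_information(net_b),
            }
        )
    df = pd.DataFrame(rows)
    phi_a, phi_b = df["phi_a"].to_numpy(), df["phi_b"].to_numpy()
    if np.std(phi_a) > 0 and np.std(phi_b) > 0:
        r, p = sps.pearsonr(phi_a, phi_b)
    else:
        r, p = float("nan"), float("nan")
    ks_phi = sps.ks_2samp(phi_a, phi_b)
    msp_a = df["mean_small_phi_a"].dropna().to_numpy()
    msp_b = df["mean_small_phi_b"].dropna().to_numpy()
    ks_msp = sps.ks_2samp(msp_a, msp_b) if len(msp_a) and len(msp_b) else None
    return {
        "pair": (str(la), str(lb)),
        "shared": shared,
        "records": df,
        "phi_pearson_r": float(r),
        "phi_pearson_p": float(p),
        "phi_ks_stat": float(ks_phi.statistic),
        "phi_ks_p": float(ks_phi.pvalue),
        "mean_small_phi_ks_stat": None if ks_msp is None else float(ks_msp.statistic),
        "mean_small_phi_ks_p": None if ks_msp is None else float(ks_msp.pvalue),
        "ei_equal": bool(np.allclose(df["ei_a"], df["ei_b"], atol=1e-9)),
        "ei_max_abs_diff": float(np.abs(df["ei_a"] - df["ei_b"]).max()),
    }


def run_binarization_correlation(
    label,
    n: int,
    seed,
    config: RunConfig = DEFAULT_CONFIG,
    methods: Sequence[str] = ("faure_kaji", "tonello"),
) -> Dict[str, object]:
    """Correlate Phi of random asymptotic multi-valued systems with Phi of
    their binarizations.

    Each sample draws an asymptotic evolution function, evaluates Phi of
    the original at the first state stored in its TPM (the successor of
    the all-zero state, which is reachable by construction), and Phi of
    each binarization at the threshold-mapped image of that state.
    Mapped states may be unreachable in a binarized system (notably under
    the Tonello construction); they are evaluated without the
    reachability requirement and flagged in the records.
    """
    label = ClassLabel.parse(label)
    rng = np.random.default_rng(seed)
    binarizers = {"faure_kaji": faure_kaji, "tonello": tonello}
    rows = []
    for k in range(n):
        f = random_asymptotic_function(label.digits, rng)
        net = f.to_network()
        state = f.successor(st.decode_state(0, label.digits))
        res = sia(net, state, config)
        row = {"sample": k, "phi_original": res.big_phi}
        for method in methods:
            b = binarizers[method](f)
            bnet = b.binary_function.to_network()
            bstate = b.map_state(state)
            idx = st.encode_state(bstate, bnet.radices)
            reachable = bool(bnet.tpm[:, idx].max() > 0)
            bres = sia(bnet, bstate, config, require_reachable=False)
            row[f"phi_{method}"] = bres.big_phi
            row[f"reachable_{method}"] = reachable
        rows.append(row)
    df = pd.DataFrame(rows)
    out: Dict[str, object] = {"class": str(label), "n": n, "records": df}
    x = df["phi_original"].to_numpy()
    for method in methods:
        y = df[f"phi_{method}"].to_numpy()
        if np.std(x) > 0 and np.std(y) > 0:
            r, p = sps.pearsonr(x, y)
        else:
            r, p = float("nan"), float("nan")
        out[f"{method}_r"] = float(r)
        out[f"{method}_p"] = float(p)
    return out
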