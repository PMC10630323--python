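"""End-to-end synthetic benchmarks exercising the full pipelines.

These drive the package exactly the way a user would, but on the built-in
generator so they run anywhere: generate paired recordings, run peak
detection and envelope detrending, pair cardiac cycles, fit the PPG-to-ECG
regression, and score held-out cycles.
"""

from __future__ import annotations

import numpy as np

from .core import Signal
from .p2e import CyclePair, P2eSpec, fit_p2e, pair_cycles
from .peaks import ECG_PROFILE, PPG_PROFILE, detect_valleys, terma_detect
from .preprocess import detrend
from .siggen import SimConfig, generate_recording

__all__ = ["make_cycle_bank", "p2e_benchmark", "detrended_pair"]


def detrended_pair(cfg: SimConfig, use_truth_peaks: bool = False):
    """Generate one recording and return detrended (ppg, ecg) with peaks.

    Peaks come from the TERMA detector by default (the method's own path);
    ground-truth fiducials can be substituted for noise-free oracle checks.
    """
    rec = generate_recording(cfg)
    green = rec.ppg.channel("green")
    ecg = rec.ecg
    if use_truth_peaks:
        p_peaks, r_peaks = rec.pulse_peaks, rec.r_peaks
    else:
        p_peaks = terma_detect(green, PPG_PROFILE)
        r_peaks = terma_detect(ecg, ECG_PROFILE)
    p_valleys = detect_valleys(green, p_peaks)
    r_valleys = detect_valleys(ecg, r_peaks)
    ppg_d = detrend(green, p_peaks, p_valleys)
    ecg_d = detrend(ecg, r_peaks, r_valleys)
    return ppg_d, ecg_d, p_peaks, r_peaks, rec


def make_cycle_bank(
    n_cycles: int,
    seed: int = 0,
    fs: float = 125.0,
    hr_range: tuple[float, float] = (55.0, 110.0),
    ptt_range: tuple[float, float] = (150.0, 250.0),
    noise_sd: float = 0.02,
    L: int = 300,
    recording_s: float = 30.0,
    use_truth_peaks: bool = False,
) -> list[CyclePair]:
    """Detrended, synchronized cycle pairs from many short synthetic sessions.

    Heart rate and pulse-transit lag are drawn per recording; each session
    contributes its complete beats until ``n_cycles`` pairs are collected.
    """
    rng = np.random.default_rng(seed)
    pairs: list[CyclePair] = []
    subject = 0
    while len(pairs) < n_cycles:
        cfg = SimConfig(
            fs=fs,
            duration=recording_s,
            hr=float(rng.uniform(*hr_range)),
            rr=float(rng.uniform(10.0, 22.0)),
            spo2=float(rng.uniform(93.0, 99.0)),
            ptt_lag=float(rng.uniform(*ptt_range)),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        try:
            ppg_d, ecg_d, p_peaks, r_peaks, _ = detrended_pair(cfg, use_truth_peaks)
            new = pair_cycles(ppg_d, ecg_d, p_peaks, r_peaks, L=L, subject=subject)
        except ValueError:
            continue  # a rare pathological detection on one session; skip it
        pairs.extend(new)
        subject += 1
    return pairs[:n_cycles]


def p2e_benchmark(
    n_train: int = 1500,
    n_test: int = 300,
    seed: int = 11,
    spec: P2eSpec | None = None,
    **bank_kwargs,
) -> dict:
    """Train the configured PPG-to-ECG model and score held-out cycles.

    Returns mean per-cycle Pearson correlation, MAE (detrended scale) and
    Dirichlet distance over the held-out cycles, plus the fitted results.
    """
    spec = spec or P2eSpec(config="ffnn")
    pairs = make_cycle_bank(n_train + n_test, seed=seed, L=spec.L, **bank_kwargs)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    test = [pairs[i] for i in perm[:n_test]]
    train = [pairs[i] for i in perm[n_test:]]
    results = fit_p2e(train, spec, seed=seed)
    ev = results.evaluate(test)
    return {
        "mean_p_corr": float(ev["p_corr"].mean()),
        "mean_mae": float(ev["mae"].mean()),
        "mean_l_dir": float(ev["l_dir"].mean()),
        "n_train": len(train),
        "n_test": len(test),
        "results": results,
        "per_cycle": ev,
    }


def make_hr_dataset(
    n_subjects: int = 60,
    duration_s: float = 41.0,
    fs: float = 25.0,
    w_s: float = 10.0,
    hr_range: tuple[float, float] = (50.0, 150.0),
    noise_sd: float = 0.05,
    seed: int = 5,
    standardize: bool = True,
):
    """Wavelet-filtered green-channel HR segments from many synthetic subjects.

    Each subject is one recording with a fixed heart rate drawn from
    ``hr_range``; segments are standardized per window (zero mean, unit
    variance) so the networks see shape, not camera gain.
    """
    from .preprocess import segment, wavelet_filter

    rng = np.random.default_rng(seed)
    full = None
    for s in range(n_subjects):
        cfg = SimConfig(
            fs=fs,
            duration=duration_s,
            hr=float(rng.uniform(*hr_range)),
            rr=float(rng.uniform(10.0, 22.0)),
            noise_sd=noise_sd,
            seed=int(rng.integers(2**31)),
        )
        rec = generate_recording(cfg)
        g = wavelet_filter(rec.ppg.channel("green"))
        ds = segment(g, rec.labels[["hr"]], w_s=w_s, subject=s)
        full = ds if full is None else full.concat(ds)
    if standardize:
        mu = full.segments.mean(axis=1, keepdims=True)
        sd = full.segments.std(axis=1, keepdims=True) + 1e-9
        full.segments = (full.segments - mu) / sd
    return full


def mtnet_hr_benchmark(seed: int = 0, max_epochs: int = 200) -> dict:
    """Train MT-Net on synthetic HR segments; report held-out MAE (beats/min)."""
    from .vitals_models import ModelSpec, TrainSpec, VitalsRegressor

    ds = make_hr_dataset(seed=5)
    spec = ModelSpec(name="mt_net", n_outputs=1, conv_filters=(8, 16, 32))
    tr = TrainSpec(max_epochs=max_epochs, patience=30, scale_labels=True, plateau_patience=15)
    res = VitalsRegressor(ds, spec, tr).fit(seed=seed)
    return {"test_mae_hr": res.test_mae["hr"], "results": res, "n_segments": len(ds)}


def clip_retrieval_benchmark(
    n_corpus: int = 2000,
    n_queries: int = 200,
    seed: int = 3,
    w_s: float = 10.0,
    fs: float = 25.0,
    k: int = 3,
) -> dict:
    """Pretrain the contrastive model on a synthetic caption corpus and
    measure top-k querying HR error on fresh segments."""
    from .siggen import gen_caption_corpus
    from .vitals_clip import VitalsClip

    corpus = gen_caption_corpus(n_corpus, seed=seed, w_s=w_s, fs=fs)
    queries = gen_caption_corpus(n_queries, seed=seed + 96, w_s=w_s, fs=fs)
    results = VitalsClip(corpus).fit(seed=seed)
    errs = []
    for q in queries:
        pred, _ = results.query(np.asarray(q["segment"]), k=k)
        errs.append(abs(pred["hr"] - q["labels"]["hr"]))
    return {
        "query_hr_mae": float(np.mean(errs)),
        "results": results,
        "n_corpus": n_corpus,
        "n_queries": n_queries,
    }
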