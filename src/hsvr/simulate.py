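"""Mechanistic synthetic-data generator for Caco-2 permeability modeling.

The generator emulates the structure attributed to Caco-2 permeation:
log P_app rises with lipophilicity up to a breakpoint and falls beyond it
(bilinear log P term), is penalized by polarity (PSA) and hydrogen-bond
donors, takes an efflux-transporter hit for aromatic, donor-rich compounds
(a threshold interaction in n_ar and HBD standing in for P-gp/BCRP
recognition), and carries per-ion-class offsets with neutral compounds the
most permeable.  Gaussian noise is added on the log10 scale.  Every run is
seeded and the true signal components are returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import errors
from .io import CompoundRecord, CompoundSet

ION_CLASS_CODES = {"acid": 0, "base": 1, "neutral": 2, "zwitterion": 3}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters.  Defaults give a signal-to-noise ratio that
    puts a well-specified model near r^2 ~ 0.9."""

    n: int = 300
    seed: int = 0
    intercept: float = -4.2  # baseline log10(P_app/(cm/s))
    logp_break: float = 3.0  # lipophilicity optimum
    slope_up: float = 0.35  # rise below the breakpoint, per log P unit
    slope_down: float = -0.40  # fall beyond it (negative)
    psa_coef: float = 0.010  # penalty per A^2 of polar surface area
    hbd_coef: float = 0.15  # penalty per hydrogen-bond donor
    efflux_penalty: float = 0.60  # hit when the transporter rule fires
    ar_thresh: int = 3  # n_ar >= ar_thresh and ...
    hbd_thresh: int = 2  # ... hbd >= hbd_thresh triggers efflux
    ion_offsets: dict = field(
        default_factory=lambda: {
            "neutral": 0.0,
            "acid": -0.35,
            "base": -0.30,
            "zwitterion": -0.55,
        }
    )
    noise_sd: float = 0.15
    class_probs: dict = field(
        default_factory=lambda: {
            "acid": 0.25,
            "base": 0.25,
            "neutral": 0.40,
            "zwitterion": 0.10,
        }
    )

    def __post_init__(self):
        if self.n < 10:
            raise errors.ValidationError("n must be >= 10")
        if self.noise_sd < 0:
            raise errors.ValidationError("noise_sd must be >= 0")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise errors.ValidationError("class_probs must sum to 1")
        if set(self.class_probs) != set(ION_CLASS_CODES):
            raise errors.ValidationError(
                f"class_probs must cover exactly {sorted(ION_CLASS_CODES)}"
            )


def closed_form(desc: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Noise-free response implied by a descriptor table under ``config``."""
    logp = desc["log_p"].to_numpy(float)
    psa = desc["psa"].to_numpy(float)
    hbd = desc["hbd"].to_numpy(float)
    n_ar = desc["n_ar"].to_numpy(float)
    efflux = (n_ar >= config.ar_thresh) & (hbd >= config.hbd_thresh)
    offsets = desc["ion_class"].map(config.ion_offsets).to_numpy(float)
    return (
        config.intercept
        + config.slope_up * np.minimum(logp, config.logp_break)
        + config.slope_down * np.maximum(logp - config.logp_break, 0.0)
        - config.psa_coef * psa
        - config.hbd_coef * hbd
        - config.efflux_penalty * efflux
        + offsets
    )


def generate(config: SimConfig | None = None) -> tuple[CompoundSet, pd.DataFrame, dict]:
    """Draw a descriptor table and responses; fully seeded and reproducible.

    Returns (compound set, descriptor matrix, truth record).  The truth
    record stores the noise-free signal, the noise draw and the efflux-rule
    indicator so recovery tests can decompose the response.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n
    ids = [f"syn{i + 1:04d}" for i in range(n)]

    classes = sorted(config.class_probs)
    probs = [config.class_probs[c] for c in classes]
    ion_class = rng.choice(classes, size=n, p=probs)

    log_p = rng.normal(2.0, 1.5, n)
    psa = rng.gamma(shape=3.0, scale=25.0, size=n)
    hbd = rng.poisson(1.5, n)
    hba = rng.poisson(4.0, n)
    n_ar = rng.poisson(1.2, n)
    n_ring = n_ar + rng.poisson(0.6, n)
    n_rot = rng.poisson(5.0, n)
    mw = np.clip(rng.normal(350.0, 90.0, n), 100.0, None)
    alpha = 0.27 * mw + rng.normal(0.0, 4.0, n)  # tracks MW almost linearly
    v_m = 0.90 * mw + rng.normal(0.0, 25.0, n)
    mu = np.abs(rng.normal(3.0, 2.0, n))
    mu_max = mu * rng.uniform(0.55, 0.95, n) + np.abs(rng.normal(0.0, 0.3, n))

    pka_max = np.empty(n)
    for cls, low, high in (
        ("acid", 3.0, 6.5),
        ("base", 7.5, 10.5),
        ("zwitterion", 7.2, 10.0),
        ("neutral", 12.0, 14.0),
    ):
        mask = ion_class == cls
        pka_max[mask] = rng.uniform(low, high, mask.sum())

    desc = pd.DataFrame(
        {
            "log_p": log_p,
            "psa": psa,
            "hbd": hbd.astype(float),
            "hba": hba.astype(float),
            "n_ar": n_ar.astype(float),
            "n_ring": n_ring.astype(float),
            "n_rot": n_rot.astype(float),
            "mw": mw,
            "alpha": alpha,
            "v_m": v_m,
            "mu": mu,
            "mu_max": mu_max,
            "pka_max": pka_max,
            "ion_class": ion_class,
            "ion_class_code": [ION_CLASS_CODES[c] for c in ion_class],
        },
        index=pd.Index(ids, name="id"),
    )

    signal = closed_form(desc, config)
    noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd > 0 else np.zeros(n)
    y = signal + noise

    records = [
        CompoundRecord(id=i, smiles=None, log_papp=float(v), ion_class=str(c))
        for i, v, c in zip(ids, y, ion_class)
    ]
    numeric = desc.drop(columns=["ion_class"])
    cset = CompoundSet(records, descriptors=numeric, provenance=f"simulated (seed={config.seed})")
    truth = {
        "config": config,
        "signal": signal,
        "noise": noise,
        "efflux": (n_ar >= config.ar_thresh) & (hbd >= config.hbd_thresh),
    }
    return cset, desc, truth


# 12-row pinned fixture: precomputed descriptors for real drug structures,
# responses given by the noise-free closed form at default parameters.
# Covers all four ion classes and one structural outlier (n_ring = 10).
_FIXTURE_ROWS = [
    # id, smiles, log_p, psa, hbd, hba, n_ar, n_ring, n_rot, mw, alpha, v_m, mu, mu_max, pka_max, ion_class
    ("fx01", "CC(=O)Oc1ccccc1C(=O)O", 1.2, 63.6, 1, 3, 1, 1, 3, 180.2, 48.6, 162.2, 2.5, 2.0, 3.5, "acid"),
    ("fx02", "CN1CCC[C@H]1c1cccnc1", 1.2, 16.1, 0, 2, 1, 2, 1, 162.2, 43.8, 146.0, 2.2, 1.8, 8.0, "base"),
    ("fx03", "Clc1ccccc1", 2.8, 0.0, 0, 0, 1, 1, 0, 112.6, 30.4, 101.3, 1.6, 1.5, 13.0, "neutral"),
    ("fx04", "NCC(=O)O", -3.2, 63.3, 2, 3, 0, 0, 1, 75.1, 20.3, 67.6, 11.0, 9.5, 9.6, "zwitterion"),
    ("fx05", "CCO", -0.3, 20.2, 1, 1, 0, 0, 0, 46.1, 12.4, 41.5, 1.7, 1.5, 13.5, "neutral"),
    ("fx06", "c1ccc2ccccc2c1", 3.3, 0.0, 0, 0, 2, 2, 0, 128.2, 34.6, 115.4, 0.0, 0.0, 13.0, "neutral"),
    ("fx07", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 3.5, 37.3, 1, 2, 1, 1, 4, 206.3, 55.7, 185.7, 1.9, 1.4, 4.9, "acid"),
    ("fx08", "CN(C)CCc1c[nH]c2ccccc12", 2.0, 19.0, 1, 2, 2, 2, 3, 188.3, 50.8, 169.5, 2.1, 1.6, 10.2, "base"),
    ("fx09", "OC(=O)c1cc(O)c(O)c(O)c1", 0.5, 98.0, 4, 5, 1, 1, 1, 170.1, 45.9, 153.1, 3.4, 2.9, 4.4, "acid"),
    # donor-rich tri-aromatic: fires the efflux rule (n_ar >= 3, hbd >= 2)
    ("fx10", "Oc1ccc(cc1)-c1ccc(O)c(-c2ccccc2O)c1", 4.2, 60.7, 3, 3, 3, 3, 2, 278.3, 75.1, 250.5, 2.8, 2.2, 9.8, "neutral"),
    # ten fused rings: trips the structural outlier rule
    ("fx11", "c1cc2ccc3ccc4ccc5ccc6ccc7ccc8ccc9ccc%10ccc1c1c2c3c4c5c6c7c8c9c%101", 9.0, 0.0, 0, 0, 10, 10, 0, 600.7, 162.2, 540.6, 0.0, 0.0, 13.0, "neutral"),
    ("fx12", "NC(=O)c1ccc[nH+]c1", -1.0, 66.0, 2, 2, 1, 1, 1, 123.1, 33.2, 110.8, 8.3, 7.1, 8.8, "zwitterion"),
]


def worked_fixture() -> tuple[CompoundSet, pd.DataFrame]:
    """Small pinned table for documentation and smoke tests.

    Twelve compounds with precomputed descriptor values; the response is
    the generator's noise-free closed form at default parameters, so the
    fixture exercises every downstream stage deterministically.
    """
    cols = [
        "log_p", "psa", "hbd", "hba", "n_ar", "n_ring", "n_rot",
        "mw", "alpha", "v_m", "mu", "mu_max", "pka_max",
    ]
    ids = [r[0] for r in _FIXTURE_ROWS]
    smiles = [r[1] for r in _FIXTURE_ROWS]
    ion_class = [r[-1] for r in _FIXTURE_ROWS]
    values = [list(r[2:-1]) for r in _FIXTURE_ROWS]
    desc = pd.DataFrame(values, columns=cols, index=pd.Index(ids, name="id"), dtype=float)
    desc["ion_class"] = ion_class
    desc["ion_class_code"] = [ION_CLASS_CODES[c] for c in ion_class]

    y = closed_form(desc, SimConfig())
    records = [
        CompoundRecord(id=i, smiles=s, log_papp=float(v), ion_class=c)
        for i, s, v, c in zip(ids, smiles, y, ion_class)
    ]
    numeric = desc.drop(columns=["ion_class"])
    return CompoundSet(records, descriptors=numeric, provenance="worked fixture"), desc
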