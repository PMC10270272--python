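"""12-lead ECG containers, file I/O and denoising.

Records are stored in millivolts as a (n_leads, n_samples) float array with an
ordered list of lead names.  Two on-disk formats are supported:

``csv``
    One header row of lead names, one column per lead, voltages in mV.  The
    sampling rate is not stored in the file and must be supplied by the caller.

``wfdb``
    Single-segment WFDB records: a text ``.hea`` header plus a format-16
    (little-endian int16) ``.dat`` signal file.  ADC gain and baseline from the
    header are honored and samples are converted to mV on read.  The writer
    uses a gain of 2000 adu/mV (0.5 µV resolution), so a write/read round trip
    is exact to 2.5e-4 mV.

Denoising is a zero-phase Butterworth bandpass (default 0.5–45 Hz, order 4,
applied forward-backward) plus a notch at the mains frequency (default 50 Hz,
Q = 30).  Zero-phase filtering is used so fiducial timing is not biased.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .errors import FilterSpecError, FormatError, LeadSetError

#: Conventional 12-lead order.
LEADS_12 = (
    "I", "II", "III", "aVR", "aVL", "aVF",
    "V1", "V2", "V3", "V4", "V5", "V6",
)

#: The 8 linearly independent leads; the remaining 4 are derived combinations.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")


@dataclass
class ECGRecord:
    """Multichannel sampled ECG voltage in mV.

    Parameters
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Per-lead voltage series in millivolts.
    lead_names : tuple of str
        Ordered lead labels matching the rows of ``samples``.
    fs : float
        Sampling rate in Hz.
    subject_id : str
        Opaque subject identifier.
    """

    samples: np.ndarray
    lead_names: tuple
    fs: float
    subject_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.lead_names = tuple(self.lead_names)
        if self.samples.ndim != 2:
            raise FormatError("samples must be a 2-D (n_leads, n_samples) array")
        if len(self.lead_names) != self.samples.shape[0]:
            raise FormatError(
                f"{len(self.lead_names)} lead names for {self.samples.shape[0]} rows"
            )
        if len(set(self.lead_names)) != len(self.lead_names):
            raise LeadSetError("duplicate lead names")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        missing = [l for l in INDEPENDENT_LEADS if l not in self.lead_names]
        if missing:
            raise LeadSetError(f"missing required leads: {', '.join(missing)}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        """Record length in seconds (n_samples / fs)."""
        return self.n_samples / self.fs

    def lead(self, name: str) -> np.ndarray:
        """Return one lead's voltage series by name."""
        try:
            return self.samples[self.lead_names.index(name)]
        except ValueError:
            raise LeadSetError(f"lead {name!r} not in record") from None


@dataclass
class FilterSpec:
    """Denoising parameters.

    ``notch_hz`` is the mains frequency (50 Hz in the acquisition setting this
    package targets; set 60 for North-American data).  The passband removes
    baseline drift below ``bandpass_lo_hz`` and EMG/motion artifact above
    ``bandpass_hi_hz``.
    """

    notch_hz: float = 50.0
    bandpass_lo_hz: float = 0.5
    bandpass_hi_hz: float = 45.0
    order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        if not (0 < self.bandpass_lo_hz < self.bandpass_hi_hz < nyq):
            raise FilterSpecError(
                f"passband {self.bandpass_lo_hz}-{self.bandpass_hi_hz} Hz invalid "
                f"for fs={fs} Hz"
            )
        if not (0 < self.notch_hz < nyq):
            raise FilterSpecError(f"notch {self.notch_hz} Hz outside (0, {nyq}) Hz")


def read_ecg(path: str, format: str = "csv", fs: float = 1000.0,
             subject_id: str | None = None) -> ECGRecord:
    """Read an ECG record from ``csv`` or ``wfdb`` format.

    For CSV the sampling rate is taken from ``fs``; for WFDB it comes from the
    header.  ``path`` for WFDB may be the record name with or without the
    ``.hea`` extension.
    """
    if subject_id is None:
        subject_id = os.path.splitext(os.path.basename(path))[0]
    if format == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed CSV, ragged rows, ...
            raise FormatError(f"cannot parse {path} as ECG CSV: {exc}") from exc
        if df.empty or any(str(c).startswith("Unnamed") for c in df.columns):
            raise FormatError(f"{path}: expected one header row of lead names")
        if df.isna().any().any():
            raise FormatError(f"{path}: inconsistent column lengths or missing values")
        names = tuple(str(c).strip() for c in df.columns)
        return ECGRecord(df.to_numpy(dtype=float).T, names, fs, subject_id)
    if format == "wfdb":
        return _read_wfdb(path, subject_id)
    raise FormatError(f"unsupported ECG format {format!r}")


def write_ecg(rec: ECGRecord, path: str, format: str = "csv") -> None:
    """Write a record so that :func:`read_ecg` recovers it."""
    if format == "csv":
        pd.DataFrame(rec.samples.T, columns=list(rec.lead_names)).to_csv(
            path, index=False, float_format="%.10g"
        )
        return
    if format == "wfdb":
        _write_wfdb(rec, path)
        return
    raise FormatError(f"unsupported ECG format {format!r}")


# -- minimal single-segment WFDB (format 16) -------------------------------

_WFDB_GAIN = 2000.0  # adu per mV -> 0.5 uV quantization


def _write_wfdb(rec: ECGRecord, path: str) -> None:
    base = path[:-4] if path.endswith(".hea") else path
    name = os.path.basename(base)
    adc = np.rint(rec.samples * _WFDB_GAIN)
    if np.abs(adc).max(initial=0) > 32767:
        raise FormatError("signal exceeds int16 range at gain 2000 adu/mV")
    adc = adc.astype("<i2")
    n_sig, n_samp = adc.shape
    lines = [f"{name} {n_sig} {rec.fs:g} {n_samp}"]
    for i, lead in enumerate(rec.lead_names):
        csum = int(np.sum(adc[i], dtype=np.int64) % 65536)
        if csum >= 32768:
            csum -= 65536
        lines.append(
            f"{name}.dat 16 {_WFDB_GAIN:g}(0)/mV 16 0 {int(adc[i, 0])} {csum} 0 {lead}"
        )
    with open(base + ".hea", "w") as fh:
        fh.write("\n".join(lines) + "\n")
    adc.T.tofile(base + ".dat")  # sample-interleaved


def _read_wfdb(path: str, subject_id: str) -> ECGRecord:
    base = path[:-4] if path.endswith(".hea") else path
    try:
        with open(base + ".hea") as fh:
            lines = [l.strip() for l in fh if l.strip() and not l.startswith("#")]
    except OSError as exc:
        raise FormatError(f"cannot read WFDB header {base}.hea: {exc}") from exc
    head = lines[0].split()
    try:
        n_sig, fs, n_samp = int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"malformed WFDB header line: {lines[0]!r}") from exc
    names, gains, baselines = [], [], []
    for spec in lines[1 : 1 + n_sig]:
        parts = spec.split()
        if parts[1] != "16":
            raise FormatError(f"only WFDB format 16 supported, got {parts[1]}")
        g = parts[2].split("/")[0]
        if "(" in g:
            g, b = g.rstrip(")").split("(")
        else:
            b = "0"
        gains.append(float(g) or 200.0)
        baselines.append(float(b))
        names.append(parts[-1])
    raw = np.fromfile(base + ".dat", dtype="<i2")
    if raw.size != n_sig * n_samp:
        raise FormatError(
            f"{base}.dat has {raw.size} samples, header declares {n_sig * n_samp}"
        )
    adc = raw.reshape(n_samp, n_sig).T.astype(float)
    mv = (adc - np.array(baselines)[:, None]) / np.array(gains)[:, None]
    return ECGRecord(mv, tuple(names), fs, subject_id)


# -- denoising --------------------------------------------------------------

def denoise(rec: ECGRecord, spec: FilterSpec | None = None) -> ECGRecord:
    """Zero-phase bandpass + mains notch over every lead.

    Returns a new record of the same shape; the input is not modified.
    """
    if spec is None:
        spec = FilterSpec()
    spec.validate(rec.fs)
    sos = signal.butter(
        spec.order,
        [spec.bandpass_lo_hz, spec.bandpass_hi_hz],
        btype="bandpass",
        fs=rec.fs,
        output="sos",
    )
    b_n, a_n = signal.iirnotch(spec.notch_hz, spec.notch_q, fs=rec.fs)
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    out = signal.filtfilt(b_n, a_n, out, axis=1)
    return replace(rec, samples=out)
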