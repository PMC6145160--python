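"""Turn a cleaned continuous EEG recording into average-referenced,
band-filtered, fixed-length epochs.

The processing order is: broadband bandpass (0.5-30 Hz) on the continuous
record, division into non-overlapping epochs (default 10 s, trailing
remainder discarded), re-referencing of each epoch to the common average,
then a zero-phase bandpass per frequency band applied epoch-wise with
1 s reflective edge padding to limit filter transients.

All filters are 4th-order Butterworth applied forward-backward
(``scipy.signal.sosfiltfilt``), i.e. zero phase shift and a magnitude
response equal to the square of the one-pass response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class PreprocessingError(ValueError):
    """Raised for invalid filter bands, epoch lengths or channel counts."""


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with edges in Hz."""

    name: str
    low: float
    high: float

    def validate(self, fs: float) -> None:
        if not (0.0 < self.low < self.high <= fs / 2.0):
            raise PreprocessingError(
                f"band {self.name!r}: need 0 < low < high <= fs/2, "
                f"got ({self.low}, {self.high}) at fs={fs}"
            )


#: Conventional EEG bands used throughout: delta, theta, alpha, beta.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 3.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

#: Broadband prefilter applied before epoching.
BROADBAND = BandDefinition("broadband", 0.5, 30.0)


@dataclass
class EpochedBandData:
    """Band-filtered epochs for one subject.

    ``epochs`` is a list of (n_channels, n_samples) arrays, all the same
    shape; after average referencing the across-channel mean of every
    sample is ~0.
    """

    band: BandDefinition
    epochs: list[np.ndarray]
    fs: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)


def bandpass_zero_phase(
    data: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = 4,
    pad_s: float | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass along the last axis.

    Parameters
    ----------
    data : array, (..., n_samples)
    fs : sampling rate in Hz
    low, high : band edges in Hz, ``0 < low < high <= fs/2``
    order : one-pass Butterworth order (applied twice, forward-backward)
    pad_s : optional reflective padding in seconds added at both ends
        before filtering and removed afterwards; used when filtering
        short epochs.
    """
    BandDefinition("bandpass", low, high).validate(fs)
    data = np.asarray(data, dtype=float)
    n = data.shape[-1]
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if pad_s is not None and pad_s > 0:
        pad = min(int(round(pad_s * fs)), n - 1)
        padded = np.concatenate(
            [
                data[..., pad:0:-1],
                data,
                data[..., -2 : -pad - 2 : -1],
            ],
            axis=-1,
        )
        out = signal.sosfiltfilt(sos, padded, axis=-1)
        return out[..., pad : pad + n]
    return signal.sosfiltfilt(sos, data, axis=-1)


def make_epochs(data: np.ndarray, fs: float, epoch_length_s: float = 10.0) -> list[np.ndarray]:
    """Cut a (channels, samples) record into consecutive non-overlapping
    epochs of ``epoch_length_s``; the trailing remainder is discarded.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n_samples = data.shape[1]
    epoch_len = int(round(epoch_length_s * fs))
    if epoch_len <= 0:
        raise PreprocessingError("epoch length must be positive")
    n_epochs = n_samples // epoch_len
    if n_epochs < 1:
        raise PreprocessingError(
            f"recording of {n_samples} samples shorter than one "
            f"{epoch_length_s}-s epoch ({epoch_len} samples)"
        )
    return [data[:, i * epoch_len : (i + 1) * epoch_len].copy() for i in range(n_epochs)]


def average_reference(epoch: np.ndarray) -> np.ndarray:
    """Re-reference to the common average: subtract, at every sample, the
    across-channel mean from every channel. Idempotent."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 2 or epoch.shape[0] < 2:
        raise PreprocessingError("average reference requires >= 2 channels")
    return epoch - epoch.mean(axis=0, keepdims=True)


def decompose_bands(
    data: np.ndarray,
    fs: float,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    epoch_length_s: float = 10.0,
    channel_labels: list[str] | None = None,
    broadband: BandDefinition = BROADBAND,
) -> dict[str, EpochedBandData]:
    """Full preprocessing chain: broadband filter -> epoch -> average
    reference -> per-band zero-phase filter (epoch-wise, 1 s reflect
    padding). Returns one :class:`EpochedBandData` per band, all with the
    same epoch count."""
    if not bands:
        raise PreprocessingError("empty band list")
    for b in bands:
        b.validate(fs)
    labels = list(channel_labels) if channel_labels is not None else []
    wide = bandpass_zero_phase(data, fs, broadband.low, broadband.high)
    epochs = [average_reference(e) for e in make_epochs(wide, fs, epoch_length_s)]
    out: dict[str, EpochedBandData] = {}
    for band in bands:
        band_epochs = [
            bandpass_zero_phase(e, fs, band.low, band.high, pad_s=1.0) for e in epochs
        ]
        out[band.name] = EpochedBandData(band=band, epochs=band_epochs, fs=fs, channel_labels=labels)
    return out
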