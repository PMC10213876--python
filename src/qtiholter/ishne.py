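"""Reader/writer for the ISHNE 1.0 Holter ECG file format.

Layout: 8-byte magic ``ISHNE1.0``, 2-byte CRC-CCITT of the header
block, a 512-byte fixed header, an optional variable-length block, and
16-bit little-endian lead-multiplexed samples scaled by a per-lead
amplitude resolution in nanovolts. A CRC mismatch is warned about, not
fatal (stale CRCs are common in circulating files); structural
problems (bad magic, truncation) raise :class:`IshneFormatError`
naming the offending offset.
"""

from __future__ import annotations

import struct
import warnings

import numpy as np

from .processing import ECGRecording

__all__ = ["IshneFormatError", "read_ishne", "write_ishne"]

MAGIC = b"ISHNE1.0"
_FIXED_HEADER_SIZE = 512
_HEADER_OFFSET = 10  # magic + CRC
_ECG_DEFAULT_OFFSET = _HEADER_OFFSET + _FIXED_HEADER_SIZE  # 522
_HDR = struct.Struct(
    "<iiiih40s40s20shh3h3h3h3hh12h12h12hh40sh80s80s88s")
assert _HDR.size == _FIXED_HEADER_SIZE


class IshneFormatError(ValueError):
    """Malformed ISHNE file."""


def _crc_ccitt(data: bytes) -> int:
    """CRC-16/CCITT-FALSE (poly 0x1021, init 0xFFFF)."""
    crc = 0xFFFF
    for byte in data:
        crc ^= byte << 8
        for _ in range(8):
            crc = ((crc << 1) ^ 0x1021 if crc & 0x8000 else crc << 1) & 0xFFFF
    return crc


def _pad(text: str, size: int) -> bytes:
    return text.encode("latin-1", "replace")[:size].ljust(size, b"\x00")


def write_ishne(
    recording: ECGRecording,
    path,
    resolution_nv: int = 1000,
    var_block: bytes = b"",
) -> None:
    """Write a recording as ISHNE 1.0.

    Samples are quantized to ``resolution_nv`` nanovolts per count
    (default 1 uV, int16 range +/-32.7 mV) and stored lead-multiplexed.
    """
    sig = np.asarray(recording.signal)
    n_leads, n_samples = sig.shape
    counts = np.clip(
        np.round(sig.astype(np.float64) * 1e6 / resolution_nv),
        -32768, 32767).astype("<i2")
    res = [0] * 12
    spec = [0] * 12
    qual = [0] * 12
    for c in range(n_leads):
        res[c] = int(resolution_nv)
    try:
        h, m, s = (int(v) for v in recording.start_time.split(":"))
    except (ValueError, AttributeError):
        h = m = s = 0
    header = _HDR.pack(
        len(var_block),  # variable-length block size
        n_samples,  # ECG size, samples per lead
        _ECG_DEFAULT_OFFSET,  # offset of variable block
        _ECG_DEFAULT_OFFSET + len(var_block),  # offset of ECG block
        1,  # file version
        _pad("", 40), _pad("", 40),
        _pad(recording.subject_id, 20),
        0, 0,
        0, 0, 0,  # birth date
        1, 1, 2000,  # record date
        1, 1, 2000,  # file date
        h, m, s,
        n_leads,
        *spec, *qual, *res,
        0,  # pacemaker
        _pad("synthetic", 40),
        int(round(recording.fs_hz)),
        _pad("", 80), _pad("", 80), _pad("", 88),
    )
    crc = _crc_ccitt(header + var_block)
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<H", crc))
        fh.write(header)
        fh.write(var_block)
        fh.write(counts.T.tobytes())  # lead-multiplexed


def read_ishne(path) -> ECGRecording:
    """Parse an ISHNE 1.0 file into an :class:`ECGRecording` (mV)."""
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _ECG_DEFAULT_OFFSET:
        raise IshneFormatError(
            f"file truncated: {len(data)} bytes, need at least "
            f"{_ECG_DEFAULT_OFFSET} for the fixed header")
    if data[:8] != MAGIC:
        raise IshneFormatError(
            f"bad magic at offset 0: {data[:8]!r} (expected {MAGIC!r})")
    (crc_stored,) = struct.unpack_from("<H", data, 8)
    fields = _HDR.unpack_from(data, _HEADER_OFFSET)
    (var_size, ecg_size, var_offset, ecg_offset, _version,
     _first, _last, subject_id, _sex, _race) = fields[:10]
    start_h, start_m, start_s = fields[19:22]
    n_leads = fields[22]
    resolutions = fields[47:59]
    fs = fields[61]

    if not (1 <= n_leads <= 12):
        raise IshneFormatError(f"implausible lead count {n_leads}")
    if fs <= 0:
        raise IshneFormatError(f"non-positive sampling rate {fs}")
    var_block = data[var_offset: var_offset + var_size]
    crc_calc = _crc_ccitt(
        data[_HEADER_OFFSET:_HEADER_OFFSET + _FIXED_HEADER_SIZE] + var_block)
    if crc_calc != crc_stored:
        warnings.warn(
            f"ISHNE header CRC mismatch (stored {crc_stored:#06x}, "
            f"computed {crc_calc:#06x}); continuing")

    expected_bytes = ecg_size * n_leads * 2
    body = data[ecg_offset:]
    if len(body) < expected_bytes:
        raise IshneFormatError(
            f"file truncated at offset {ecg_offset + len(body)}: ECG block "
            f"needs {expected_bytes} bytes, found {len(body)}")
    counts = np.frombuffer(body[:expected_bytes], dtype="<i2")
    counts = counts.reshape(ecg_size, n_leads).T
    res = np.array(resolutions[:n_leads], dtype=np.float64)
    res[res <= 0] = 1000.0
    signal = (counts.astype(np.float32)
              * (res[:, None].astype(np.float32) / 1e6))
    return ECGRecording(
        signal=signal,
        fs_hz=float(fs),
        start_time=f"{start_h:02d}:{start_m:02d}:{start_s:02d}",
        channel_labels=[f"ch{c + 1}" for c in range(n_leads)],
        subject_id=subject_id.rstrip(b"\x00 ").decode("latin-1"),
    )
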