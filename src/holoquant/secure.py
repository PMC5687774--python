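"""Personalised image encryption and single-level 2D wavelet compression.

Encryption follows the classical confusion/diffusion pairing: a passcode is
encoded over a 36-symbol alphabet (digits then letters), the base-36 value of
the code sequence seeds a deterministic PRNG, pixel positions are permuted by
a Fisher-Yates shuffle (confusion) and 8-bit values are XORed with a
key-derived keystream (diffusion).  Both steps are exactly invertible with
the matching key.

Compression is a single-level 2D discrete wavelet transform per channel
(Haar or 4-tap Daubechies): the approximation subband is kept in full, the
detail coefficients are hard-thresholded to the top ``keep_fraction`` by
magnitude, survivors are uniformly quantised to 16 bits and deflate-coded.
Transfer payloads are compressed first, then the coefficient byte stream is
encrypted — permuting pixels before the transform would destroy the spatial
smoothness the wavelet exploits.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass

import numpy as np
import pywt

__all__ = [
    "PasscodeKey",
    "SecurePayload",
    "derive_key",
    "encrypt",
    "decrypt",
    "compress",
    "decompress",
    "pack",
    "unpack",
    "psnr",
]

_ALPHABET = "0123456789abcdefghijklmnopqrstuvwxyz"
_WAVELETS = {"haar": "haar", "daubechies": "db2", "daubechies-4": "db2", "db2": "db2"}
_MAGIC = b"HSPAYLD1"


@dataclass(frozen=True)
class PasscodeKey:
    codes: tuple[int, ...]
    derived_seed: int


def derive_key(passcode: str) -> PasscodeKey:
    """Encode a passcode over the 36-symbol alphanumeric alphabet.

    ``codes[i]`` is the alphabet index of character i (0-9 -> 0-9,
    a-z -> 10-35, case folded); the seed is the big-endian base-36 value of
    the code sequence reduced modulo 2**32.
    """
    if not passcode:
        raise ValueError("passcode must be non-empty")
    folded = passcode.lower()
    try:
        codes = tuple(_ALPHABET.index(ch) for ch in folded)
    except ValueError:
        bad = next(ch for ch in folded if ch not in _ALPHABET)
        raise ValueError(f"passcode character {bad!r} outside [a-z0-9]") from None
    value = 0
    for c in codes:
        value = value * 36 + c
    return PasscodeKey(codes=codes, derived_seed=value % 2**32)


def _to_uint8(image: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        return arr, False
    return (np.clip(arr, 0.0, 1.0) * 255).round().astype(np.uint8), True


def _keystream(key: PasscodeKey, n: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((key.derived_seed, 0xD1F)))
    return rng.integers(0, 256, size=n, dtype=np.uint8)


def _permutation(key: PasscodeKey, n: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((key.derived_seed, 0xC0F)))
    return rng.permutation(n)


def encrypt(image: np.ndarray, key: PasscodeKey, diffuse: bool = True) -> np.ndarray:
    """Permute pixel positions and (optionally) XOR with the keystream.

    Accepts float images in [0, 1] (quantised to 8 bits) or uint8 arrays;
    returns an array of the same shape and dtype family as the 8-bit data.
    """
    data, was_float = _to_uint8(image)
    if data.size == 0:
        raise ValueError("cannot encrypt an empty image")
    flat = data.ravel()[_permutation(key, data.size)]
    if diffuse:
        flat = flat ^ _keystream(key, data.size)
    out = flat.reshape(data.shape)
    return out.astype(float) / 255.0 if was_float else out


def decrypt(payload: np.ndarray, key: PasscodeKey, diffuse: bool = True) -> np.ndarray:
    """Exact inverse of :func:`encrypt` under the matching key."""
    data, was_float = _to_uint8(payload)
    if data.size == 0:
        raise ValueError("cannot decrypt an empty payload")
    flat = data.ravel()
    if diffuse:
        flat = flat ^ _keystream(key, data.size)
    perm = _permutation(key, data.size)
    out = np.empty_like(flat)
    out[perm] = flat
    out = out.reshape(data.shape)
    return out.astype(float) / 255.0 if was_float else out


# ---------------------------------------------------------------------------
# Wavelet codec
# ---------------------------------------------------------------------------

@dataclass
class SecurePayload:
    cipher_data: bytes
    wavelet_name: str
    threshold_spec: float  # detail-coefficient keep fraction
    original_shape: tuple[int, int, int]
    quantised: bool
    encrypted: bool = False

    @property
    def compression_ratio(self) -> float:
        raw = int(np.prod(self.original_shape))
        return raw / max(len(self.cipher_data), 1)


def _resolve_wavelet(name: str) -> str:
    try:
        return _WAVELETS[name.lower()]
    except KeyError:
        raise ValueError(f"unknown wavelet {name!r}; choose from {sorted(set(_WAVELETS))}") from None


def compress(
    image: np.ndarray,
    wavelet: str = "haar",
    keep_fraction: float = 0.05,
    quantise: bool = True,
) -> SecurePayload:
    """Single-level 2D DWT compression of an RGB image in [0, 1].

    The approximation subband is stored in full; detail coefficients are
    hard-thresholded to retain the top ``keep_fraction`` by absolute value.
    With ``quantise`` the coefficients are stored as 16-bit integers with a
    per-subband scale; without it they are stored as float64 (lossless at
    keep_fraction=1 up to 8-bit rounding).
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in (0, 1]")
    wav = _resolve_wavelet(wavelet)
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = img[:, :, None]
    h, w, nch = img.shape

    subbands = []  # per channel: (cA, cH, cV, cD)
    all_details = []
    for ch in range(nch):
        cA, (cH, cV, cD) = pywt.dwt2(img[:, :, ch], wav, mode="periodization")
        subbands.append((cA, cH, cV, cD))
        all_details.extend([cH.ravel(), cV.ravel(), cD.ravel()])
    detail_mag = np.abs(np.concatenate(all_details))
    if keep_fraction < 1.0 and detail_mag.size:
        k = int(np.floor(keep_fraction * detail_mag.size))
        if k == 0:
            threshold = np.inf
        else:
            threshold = np.partition(detail_mag, detail_mag.size - k)[detail_mag.size - k]
    else:
        threshold = 0.0

    blob = bytearray()
    scales = []
    for cA, cH, cV, cD in subbands:
        for sub, is_detail in ((cA, False), (cH, True), (cV, True), (cD, True)):
            data = sub.copy()
            if is_detail and threshold > 0:
                data[np.abs(data) < threshold] = 0.0
            if quantise:
                scale = float(np.max(np.abs(data))) or 1.0
                q = (np.round(data / scale * 127) + 128).astype(np.uint8).ravel()
                # wraparound delta coding: smooth subbands become near-zero
                # byte streams that deflate collapses
                delta = np.diff(q, prepend=np.uint8(128))
                scales.append(scale)
                blob += delta.tobytes()
            else:
                scales.append(1.0)
                blob += data.astype("<f8").tobytes()

    meta = {
        "wavelet": wav,
        "keep_fraction": keep_fraction,
        "shape": [h, w, nch],
        "sub_shape": list(subbands[0][0].shape),
        "scales": scales,
        "quantised": quantise,
    }
    meta_bytes = json.dumps(meta).encode()
    payload = struct.pack("<I", len(meta_bytes)) + meta_bytes + zlib.compress(bytes(blob), level=9)
    return SecurePayload(
        cipher_data=bytes(payload),
        wavelet_name=wav,
        threshold_spec=keep_fraction,
        original_shape=(h, w, nch),
        quantised=quantise,
    )


def decompress(payload: SecurePayload) -> np.ndarray:
    """Inverse DWT of the decoded coefficients, clipped to [0, 1]."""
    if payload.encrypted:
        raise ValueError("payload is still encrypted; unpack with the key first")
    data = payload.cipher_data
    try:
        (meta_len,) = struct.unpack("<I", data[:4])
        meta = json.loads(data[4 : 4 + meta_len].decode())
        blob = zlib.decompress(data[4 + meta_len :])
    except (struct.error, json.JSONDecodeError, zlib.error, UnicodeDecodeError) as exc:
        raise ValueError(f"corrupted payload: {exc}") from exc
    h, w, nch = meta["shape"]
    sh, sw = meta["sub_shape"]
    n_sub = sh * sw
    itemsize = 1 if meta["quantised"] else 8
    out = np.empty((h, w, nch))
    pos = 0
    scales = iter(meta["scales"])
    for ch in range(nch):
        subs = []
        for _ in range(4):
            raw = blob[pos : pos + n_sub * itemsize]
            pos += n_sub * itemsize
            scale = next(scales)
            if meta["quantised"]:
                delta = np.frombuffer(raw, dtype=np.uint8)
                q = (np.cumsum(delta.astype(np.uint64)) + 128) % 256  # undo wraparound delta
                sub = (q.astype(float) - 128.0).reshape(sh, sw) * scale / 127
            else:
                sub = np.frombuffer(raw, dtype="<f8").reshape(sh, sw)
            subs.append(sub)
        out[:, :, ch] = pywt.idwt2((subs[0], tuple(subs[1:])), meta["wavelet"], mode="periodization")[:h, :w]
    return np.clip(out, 0.0, 1.0)


def psnr(reference: np.ndarray, reconstructed: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for unit-range images."""
    mse = float(np.mean((np.asarray(reference, float) - np.asarray(reconstructed, float)) ** 2))
    return float("inf") if mse == 0 else float(10 * np.log10(1.0 / mse))


# ---------------------------------------------------------------------------
# Pack / unpack: compress then encrypt the coefficient byte stream
# ---------------------------------------------------------------------------

def pack(image: np.ndarray, key: PasscodeKey, wavelet: str = "haar", keep_fraction: float = 0.05,
         quantise: bool = True) -> SecurePayload:
    """Compress an image, then encrypt the payload bytes with the key."""
    payload = compress(image, wavelet, keep_fraction, quantise)
    data = np.frombuffer(payload.cipher_data, dtype=np.uint8)
    cipher = encrypt(data, key)
    payload.cipher_data = cipher.tobytes()
    payload.encrypted = True
    return payload


def unpack(payload: SecurePayload, key: PasscodeKey) -> np.ndarray:
    """Decrypt the payload bytes with the key, then decompress."""
    if not payload.encrypted:
        return decompress(payload)
    data = np.frombuffer(payload.cipher_data, dtype=np.uint8)
    plain = decrypt(data, key)
    clear = SecurePayload(
        cipher_data=plain.tobytes(),
        wavelet_name=payload.wavelet_name,
        threshold_spec=payload.threshold_spec,
        original_shape=payload.original_shape,
        quantised=payload.quantised,
        encrypted=False,
    )
    return decompress(clear)


def write_payload(path, payload: SecurePayload) -> None:
    """Serialise a payload: 16-byte magic/version header, JSON metadata
    block, then the coefficient byte stream."""
    meta = {
        "wavelet": payload.wavelet_name,
        "keep_fraction": payload.threshold_spec,
        "shape": list(payload.original_shape),
        "quantised": payload.quantised,
        "encrypted": payload.encrypted,
    }
    meta_bytes = json.dumps(meta).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC.ljust(16, b"\0"))
        fh.write(struct.pack("<I", len(meta_bytes)))
        fh.write(meta_bytes)
        fh.write(payload.cipher_data)


def read_payload(path) -> SecurePayload:
    with open(path, "rb") as fh:
        header = fh.read(16)
        if header[:8] != _MAGIC:
            raise ValueError("not a holoquant secure payload (bad magic)")
        (meta_len,) = struct.unpack("<I", fh.read(4))
        meta = json.loads(fh.read(meta_len).decode())
        data = fh.read()
    return SecurePayload(
        cipher_data=data,
        wavelet_name=meta["wavelet"],
        threshold_spec=meta["keep_fraction"],
        original_shape=tuple(meta["shape"]),
        quantised=meta["quantised"],
        encrypted=meta["encrypted"],
    )
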