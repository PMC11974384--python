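"""Anisotropic 3D residual U-net, implemented directly on numpy.

The architecture follows the anisotropic residual U-net family used for
serial-section EM segmentation: an encoder/decoder with five levels of 28,
36, 48, 64 and 80 channels, max pooling restricted to the XY plane (section
spacing is much coarser than in-plane resolution, so the Z extent is
preserved through every stage), per-level blocks of one in-plane (1,3,3)
convolution followed by two (3,3,3) convolutions with an additive residual
connection from the output of the first convolutional module to the output
of the third, and a single (1,5,5) boundary convolution at the entry plus its
mirror before the output layer.  The native input patch is (18, 160, 160) in
(z, y, x), and the output is one logit per voxel (binary segmentation; one
trained network per organelle class).

Forward *and* backward passes are hand-written (im2col convolutions, XY max
pooling with argmax scatter, instance normalization, ELU) so that training
runs on plain numpy; correctness of every gradient is established by
finite-difference checks in the test suite.  All convolutions use "same"
padding so spatial shapes are preserved.

A :class:`WeightState` is an ordered dict of named parameter arrays plus a
provenance tag; two weight states built from the same :class:`NetworkSpec`
are structurally interchangeable, which is exactly the mechanism transfer
learning relies on: weights pretrained on one task load into a network for
any other task with the same spec.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from itertools import product
from pathlib import Path
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "NetworkSpec",
    "WeightState",
    "ResUNet3d",
    "build_network",
    "forward",
    "save_weights",
    "load_weights",
    "FULL_SPEC",
    "REDUCED_SPEC",
]

_DTYPE = np.float32  # training dtype; gradient checks override with float64


# ---------------------------------------------------------------------------
# network specification


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the network; hashable for checkpoints.

    ``levels`` are encoder channel counts top to bottom; there are
    ``len(levels) - 1`` XY-only 2x2 pooling stages, so the input XY extents
    must be divisible by ``2**(len(levels)-1)``.  Kernels are stored (z,y,x).
    """

    levels: tuple[int, ...] = (28, 36, 48, 64, 80)
    input_patch: tuple[int, int, int] = (18, 160, 160)
    boundary_kernel: tuple[int, int, int] = (1, 5, 5)
    plane_kernel: tuple[int, int, int] = (1, 3, 3)
    volume_kernel: tuple[int, int, int] = (3, 3, 3)
    out_channels: int = 1
    use_norm: bool = False  # optional instance norm inside blocks

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(int(c) for c in self.levels))
        object.__setattr__(self, "input_patch", tuple(int(s) for s in self.input_patch))
        if len(self.levels) < 2:
            raise ValueError("at least 2 levels are required")
        if min(self.levels) < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        self.check_input_shape(self.input_patch)

    @property
    def n_pools(self) -> int:
        return len(self.levels) - 1

    def check_input_shape(self, shape) -> None:
        """Raise if an input shape violates the XY divisibility constraint."""
        if len(shape) != 3 or min(int(s) for s in shape) < 1:
            raise ValueError(f"input shape must be 3 positive ints (z,y,x), got {shape!r}")
        div = 2**self.n_pools
        for axis, name in ((1, "Y"), (2, "X")):
            if shape[axis] % div != 0:
                raise ValueError(
                    f"{name} extent {shape[axis]} not divisible by {div} "
                    f"(required by {self.n_pools} XY pooling stages)"
                )

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


#: The native configuration: 5 levels, (18,160,160) patches.
FULL_SPEC = NetworkSpec()

#: Desk-scale preset for CPU runs: 3 levels, (8,32,32) patches.
REDUCED_SPEC = NetworkSpec(levels=(6, 10, 14), input_patch=(8, 32, 32))


@dataclass
class WeightState:
    """Named parameter blocks for one NetworkSpec, with provenance.

    Provenance is ``random-init``, ``pretrained:<task>`` or
    ``fine-tuned:<task>``.
    """

    params: dict[str, np.ndarray]
    spec: NetworkSpec
    provenance: str = "random-init"

    def copy(self) -> "WeightState":
        return WeightState(
            params={k: v.copy() for k, v in self.params.items()},
            spec=self.spec,
            provenance=self.provenance,
        )


# ---------------------------------------------------------------------------
# layers (each caches what its backward pass needs)

_CHUNK_TARGET = 48_000_000  # bytes of im2col buffer per chunk


class Conv3d:
    """Same-padding 3D convolution via chunked im2col + GEMM."""

    def __init__(self, name: str, in_ch: int, out_ch: int, kernel: tuple[int, int, int]):
        self.name = name
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.W: np.ndarray | None = None  # (out, in, kz, ky, kx)
        self.b: np.ndarray | None = None
        self.dW: np.ndarray | None = None
        self.db: np.ndarray | None = None

    def init(self, rng: np.random.Generator, dtype=_DTYPE) -> None:
        kz, ky, kx = self.kernel
        fan_in = self.in_ch * kz * ky * kx
        scale = np.sqrt(2.0 / fan_in)  # He init, suits ELU-family activations
        self.W = (rng.normal(0.0, scale, size=(self.out_ch, self.in_ch, kz, ky, kx))).astype(dtype)
        self.b = np.zeros(self.out_ch, dtype=dtype)

    def _pads(self):
        return tuple(k // 2 for k in self.kernel)

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, Z, Y, X = x.shape
        assert C == self.in_ch, (self.name, C, self.in_ch)
        kz, ky, kx = self.kernel
        pz, py, px = self._pads()
        xp = np.pad(x, ((0, 0), (0, 0), (pz, pz), (py, py), (px, px)))
        self._xp = xp
        win = sliding_window_view(xp, (kz, ky, kx), axis=(2, 3, 4))  # (N,C,Z,Y,X,kz,ky,kx)
        Wmat = self.W.reshape(self.out_ch, -1)
        out = np.empty((N, self.out_ch, Z, Y, X), dtype=x.dtype)
        K = C * kz * ky * kx
        cz = max(1, _CHUNK_TARGET // max(1, N * Y * X * K * x.dtype.itemsize))
        for z0 in range(0, Z, cz):
            z1 = min(Z, z0 + cz)
            cols = np.ascontiguousarray(
                win[:, :, z0:z1].transpose(0, 2, 3, 4, 1, 5, 6, 7)
            ).reshape(-1, K)
            oc = cols @ Wmat.T + self.b
            out[:, :, z0:z1] = oc.reshape(N, z1 - z0, Y, X, self.out_ch).transpose(0, 4, 1, 2, 3)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        N, C = xp.shape[0], self.in_ch
        kz, ky, kx = self.kernel
        pz, py, px = self._pads()
        Z, Y, X = dy.shape[2:]
        Wmat = self.W.reshape(self.out_ch, -1)
        K = C * kz * ky * kx
        dW = np.zeros_like(Wmat, dtype=np.float64)
        dxp = np.zeros_like(xp)
        win = sliding_window_view(xp, (kz, ky, kx), axis=(2, 3, 4))
        cz = max(1, _CHUNK_TARGET // max(1, N * Y * X * K * xp.dtype.itemsize))
        for z0 in range(0, Z, cz):
            z1 = min(Z, z0 + cz)
            zc = z1 - z0
            cols = np.ascontiguousarray(
                win[:, :, z0:z1].transpose(0, 2, 3, 4, 1, 5, 6, 7)
            ).reshape(-1, K)
            dyc = np.ascontiguousarray(dy[:, :, z0:z1].transpose(0, 2, 3, 4, 1)).reshape(-1, self.out_ch)
            dW += dyc.T.astype(np.float64) @ cols.astype(np.float64)
            dcols = (dyc @ Wmat).reshape(N, zc, Y, X, C, kz, ky, kx)
            dcols = dcols.transpose(0, 4, 1, 2, 3, 5, 6, 7)  # (N,C,zc,Y,X,kz,ky,kx)
            for a, b, c in product(range(kz), range(ky), range(kx)):
                dxp[:, :, z0 + a : z0 + a + zc, b : b + Y, c : c + X] += dcols[..., a, b, c]
        self.dW = dW.reshape(self.W.shape).astype(self.W.dtype)
        self.db = dy.sum(axis=(0, 2, 3, 4)).astype(self.b.dtype)
        del self._xp
        return dxp[:, :, pz : pz + Z, py : py + Y, px : px + X]

    def param_items(self):
        return [(f"{self.name}.W", "W", "dW"), (f"{self.name}.b", "b", "db")]


class InstanceNorm:
    """Per-sample, per-channel normalization over (Z,Y,X) with affine params."""

    eps = 1e-5

    def __init__(self, name: str, channels: int):
        self.name = name
        self.channels = channels
        self.g: np.ndarray | None = None
        self.b: np.ndarray | None = None
        self.dg: np.ndarray | None = None
        self.db: np.ndarray | None = None

    def init(self, rng, dtype=_DTYPE) -> None:
        self.g = np.ones(self.channels, dtype=dtype)
        self.b = np.zeros(self.channels, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        ax = (2, 3, 4)
        mu = x.mean(axis=ax, keepdims=True)
        var = x.var(axis=ax, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._xhat, self._inv = xhat, inv
        return self.g[None, :, None, None, None] * xhat + self.b[None, :, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ax = (2, 3, 4)
        xhat, inv = self._xhat, self._inv
        m = float(np.prod(dy.shape[2:]))
        g = self.g[None, :, None, None, None]
        dxhat = dy * g
        self.dg = (dy * xhat).sum(axis=(0, 2, 3, 4)).astype(self.g.dtype)
        self.db = dy.sum(axis=(0, 2, 3, 4)).astype(self.b.dtype)
        dx = (
            inv / m
            * (m * dxhat - dxhat.sum(axis=ax, keepdims=True) - xhat * (dxhat * xhat).sum(axis=ax, keepdims=True))
        )
        del self._xhat, self._inv
        return dx.astype(dy.dtype)

    def param_items(self):
        return [(f"{self.name}.g", "g", "dg"), (f"{self.name}.b", "b", "db")]


class ELU:
    alpha = 1.0

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0)))
        self._x, self._out = x, out
        return out.astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        grad = np.where(self._x > 0, 1.0, self._out + self.alpha)
        del self._x, self._out
        return (dy * grad).astype(dy.dtype)


class MaxPoolXY:
    """2x2 max pooling in the XY plane only; Z is untouched."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, Z, Y, X = x.shape
        if Y % 2 or X % 2:
            raise ValueError(f"XY extents must be even for pooling, got {(Y, X)}")
        v = x.reshape(N, C, Z, Y // 2, 2, X // 2, 2).transpose(0, 1, 2, 3, 5, 4, 6).reshape(
            N, C, Z, Y // 2, X // 2, 4
        )
        self._idx = v.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(v, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, Z, Y, X = self._shape
        v = np.zeros((N, C, Z, Y // 2, X // 2, 4), dtype=dy.dtype)
        np.put_along_axis(v, self._idx[..., None], dy[..., None], axis=-1)
        out = v.reshape(N, C, Z, Y // 2, X // 2, 2, 2).transpose(0, 1, 2, 3, 5, 4, 6).reshape(N, C, Z, Y, X)
        del self._idx, self._shape
        return out


class UpsampleXY:
    """2x nearest-neighbour upsampling in XY (mirror of the pooling)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, Z, Y, X = dy.shape
        return dy.reshape(N, C, Z, Y // 2, 2, X // 2, 2).sum(axis=(4, 6))


class ResBlock:
    """One level: (1,3,3) conv, then two (3,3,3) convs, residual from the
    output of the first module to the output of the third."""

    def __init__(self, name: str, in_ch: int, ch: int, spec: NetworkSpec):
        self.name = name
        self.convA = Conv3d(f"{name}.convA", in_ch, ch, spec.plane_kernel)
        self.convB = Conv3d(f"{name}.convB", ch, ch, spec.volume_kernel)
        self.convC = Conv3d(f"{name}.convC", ch, ch, spec.volume_kernel)
        self.use_norm = spec.use_norm
        if self.use_norm:
            self.normA = InstanceNorm(f"{name}.normA", ch)
            self.normB = InstanceNorm(f"{name}.normB", ch)
            self.normC = InstanceNorm(f"{name}.normC", ch)
        self.actA, self.actB, self.actC = ELU(), ELU(), ELU()

    def layers(self):
        out = [self.convA, self.convB, self.convC]
        if self.use_norm:
            out += [self.normA, self.normB, self.normC]
        return out

    def init(self, rng, dtype=_DTYPE) -> None:
        for l in self.layers():
            l.init(rng, dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        a = self.convA.forward(x)
        if self.use_norm:
            a = self.normA.forward(a)
        a = self.actA.forward(a)
        h = self.convB.forward(a)
        if self.use_norm:
            h = self.normB.forward(h)
        h = self.actB.forward(h)
        c = self.convC.forward(h)
        if self.use_norm:
            c = self.normC.forward(c)
        return self.actC.forward(c + a)  # residual: first module -> third

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.actC.backward(dy)
        da_res = d  # residual branch gradient
        if self.use_norm:
            d = self.normC.backward(d)
        d = self.convC.backward(d)
        d = self.actB.backward(d)
        if self.use_norm:
            d = self.normB.backward(d)
        d = self.convB.backward(d)
        d = d + da_res
        d = self.actA.backward(d)
        if self.use_norm:
            d = self.normA.backward(d)
        return self.convA.backward(d)


# ---------------------------------------------------------------------------
# the network


class ResUNet3d:
    """Encoder/decoder with XY-only pooling and same-level skip connections."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        ch = spec.levels
        self.stem = Conv3d("stem", 1, ch[0], spec.boundary_kernel)
        self.enc = [ResBlock(f"enc{i}", ch[i - 1] if i else ch[0], ch[i], spec) for i in range(len(ch))]
        self.pools = [MaxPoolXY() for _ in range(spec.n_pools)]
        self.ups = [UpsampleXY() for _ in range(spec.n_pools)]
        # decoder level i consumes upsampled level i+1 concatenated with the
        # encoder skip at level i
        self.dec = [
            ResBlock(f"dec{i}", ch[i + 1] + ch[i], ch[i], spec) for i in range(len(ch) - 1)
        ]
        self.head = Conv3d("head", ch[0], spec.out_channels, spec.boundary_kernel)

    # -- parameter plumbing ------------------------------------------------

    def _all_layers(self):
        out = [self.stem]
        for b in self.enc:
            out += b.layers()
        for b in self.dec:
            out += b.layers()
        out.append(self.head)
        return out

    def param_entries(self) -> list[tuple[str, object, str, str]]:
        entries = []
        for layer in self._all_layers():
            for name, attr, gattr in layer.param_items():
                entries.append((name, layer, attr, gattr))
        return entries

    def init(self, seed: int, dtype=_DTYPE) -> None:
        rng = np.random.default_rng(seed)
        self.stem.init(rng, dtype)
        for b in self.enc:
            b.init(rng, dtype)
        for b in self.dec:
            b.init(rng, dtype)
        self.head.init(rng, dtype)

    def get_weights(self, provenance: str = "random-init") -> WeightState:
        params = {name: getattr(layer, attr).copy() for name, layer, attr, _ in self.param_entries()}
        return WeightState(params=params, spec=self.spec, provenance=provenance)

    def set_weights(self, ws: WeightState) -> None:
        if ws.spec.hash() != self.spec.hash():
            raise ValueError(
                f"weight state built for spec {ws.spec.hash()} cannot load into spec {self.spec.hash()}"
            )
        entries = self.param_entries()
        names = {n for n, *_ in entries}
        if names != set(ws.params):
            raise ValueError("parameter name mismatch between weights and network")
        for name, layer, attr, _ in entries:
            setattr(layer, attr, ws.params[name].copy())

    # -- forward / backward ------------------------------------------------

    def forward(
        self, x: np.ndarray, return_features: bool = False
    ) -> np.ndarray | tuple[np.ndarray, list[np.ndarray]]:
        """Logits for a batch (N,1,Z,Y,X) or a single (Z,Y,X) patch.

        ``return_features`` additionally yields the per-level encoder feature
        maps (useful for asserting Z-extent preservation).
        """
        single = x.ndim == 3
        if single:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        if x.shape[1] != 1:
            raise ValueError(f"expected single-channel input, got {x.shape}")
        self.spec.check_input_shape(x.shape[2:])

        h = self.stem.forward(x)
        skips = []
        feats = []
        for i, block in enumerate(self.enc):
            h = block.forward(h)
            feats.append(h)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h)
        self._cat_channels = []
        for i in reversed(range(len(self.dec))):
            u = self.ups[i].forward(h)
            h = np.concatenate([u, skips[i]], axis=1)
            self._cat_channels.append((i, u.shape[1]))
            h = self.dec[i].forward(h)
        logits = self.head.forward(h)
        if single:
            out = logits[0, 0]
        elif logits.shape[1] == 1:
            out = logits[:, 0]
        else:  # pragma: no cover - out_channels is 1 throughout
            out = logits
        if return_features:
            return out, feats
        return out

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients for the last forward batch."""
        d = dlogits
        if d.ndim == 3:
            d = d[None, None]
        elif d.ndim == 4:
            d = d[:, None]
        d = self.head.backward(d)
        dskips: dict[int, np.ndarray] = {}
        for i, cat_ch in self._cat_channels[::-1]:
            d = self.dec[i].backward(d)
            du, dskip = d[:, :cat_ch], d[:, cat_ch:]
            dskips[i] = dskip
            d = self.ups[i].backward(du)
        for i in reversed(range(len(self.enc))):
            if i < len(self.pools):
                d = self.pools[i].backward(d)
                d = d + dskips[i]
            d = self.enc[i].backward(d)
        self.stem.backward(d)

    def zero_grad(self) -> None:
        for _, layer, _, gattr in self.param_entries():
            setattr(layer, gattr, None)


# ---------------------------------------------------------------------------
# functional surface


def build_network(spec: NetworkSpec, seed: int = 0) -> WeightState:
    """Randomly initialized weights for ``spec``; same seed, same weights."""
    net = ResUNet3d(spec)
    net.init(seed)
    return net.get_weights("random-init")


def forward(weights: WeightState, patch: np.ndarray) -> np.ndarray:
    """One inference pass; output shape equals input shape (one logit/voxel)."""
    net = ResUNet3d(weights.spec)
    net.set_weights(weights)
    return net.forward(np.asarray(patch, dtype=_DTYPE))


def save_weights(ws: WeightState, path: str | Path) -> None:
    """Checkpoint: parameter blocks + spec JSON + spec hash + provenance."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"spec": asdict(ws.spec), "spec_hash": ws.spec.hash(), "provenance": ws.provenance}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **ws.params)


def load_weights(path: str | Path, expect_spec: NetworkSpec | None = None) -> WeightState:
    """Load a checkpoint, verifying the embedded spec hash."""
    with np.load(Path(path) if str(path).endswith(".npz") else str(path) + ".npz") as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        params = {k: data[k] for k in data.files if k != "__meta__"}
    spec_dict = meta["spec"]
    spec_dict["levels"] = tuple(spec_dict["levels"])
    for k in ("input_patch", "boundary_kernel", "plane_kernel", "volume_kernel"):
        spec_dict[k] = tuple(spec_dict[k])
    spec = NetworkSpec(**spec_dict)
    if spec.hash() != meta["spec_hash"]:
        raise ValueError("checkpoint spec hash mismatch (corrupted file)")
    if expect_spec is not None and expect_spec.hash() != spec.hash():
        raise ValueError(
            f"checkpoint was built for spec {spec.hash()}, expected {expect_spec.hash()}"
        )
    return WeightState(params=params, spec=spec, provenance=meta["provenance"])
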