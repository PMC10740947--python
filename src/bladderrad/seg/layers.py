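"""Minimal CPU neural-network layers with explicit forward/backward passes.

Only what the U-shaped segmentation network needs: 2D convolution, 4x4 /
stride-2 transpose convolution, batch normalization, ReLU, 2x2 max pooling,
channel concatenation, sigmoid, and an Adam optimizer with L2 weight decay.

Internally everything runs channel-last (NHWC) in float32: im2col then
reduces to cheap contiguous block copies plus one BLAS matmul per layer,
which is what keeps single-CPU training practical.  All computation is
plain numpy and fully deterministic given the initialization rng.

Layers follow a simple protocol: ``forward(x, train)`` caches what the
backward pass needs; ``backward(dout)`` returns ``dx`` and stores parameter
gradients in ``grads`` aligned with ``params``.
"""

from __future__ import annotations

import numpy as np

F = np.float32


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def __getstate__(self):
        # drop transient caches / scratch buffers when pickling
        return {k: v for k, v in self.__dict__.items()
                if not k.startswith("_")}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, 'same' padding by default (NHWC)."""

    def __init__(self, cin, cout, k=3, pad=None, rng=None, bias=True):
        super().__init__()
        self.k = k
        self.cin, self.cout = cin, cout
        self.pad = (k // 2) if pad is None else pad
        scale = np.sqrt(2.0 / (cin * k * k))
        # weight layout (k*k*cin, cout) so forward is a single matmul
        self.w = rng.normal(0, scale, size=(k * k * cin, cout)).astype(F)
        self.b = np.zeros(cout, dtype=F) if bias else None
        self.params = [self.w] + ([self.b] if bias else [])

    def _buf(self, name, shape):
        # scratch buffers are reused across iterations: repeated large
        # allocations are expensive on the memory-bound CPU path
        buf = getattr(self, name, None)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=F)
            setattr(self, name, buf)
        return buf

    def forward(self, x, train=True):
        p, k, c = self.pad, self.k, self.cin
        b, h, w, _ = x.shape
        if k == 1:
            self._cols = x.reshape(b * h * w, c)
            self._hw = (h, w)
            out = self._cols @ self.w
            if self.b is not None:
                out += self.b
            return out.reshape(b, h, w, self.cout)
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
        ho, wo = xp.shape[1] - k + 1, xp.shape[2] - k + 1
        cols = self._buf("_cols_buf", (b, ho, wo, k * k, c))
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i * k + j, :] = xp[:, i:i + ho, j:j + wo, :]
        self._cols = cols.reshape(b * ho * wo, k * k * c)
        self._hw = (ho, wo)
        self._xshape = x.shape
        out = self._buf("_out_buf", (b * ho * wo, self.cout))
        np.matmul(self._cols, self.w, out=out)
        if self.b is not None:
            out += self.b
        return out.reshape(b, ho, wo, self.cout)

    def backward(self, dout):
        k, p, c = self.k, self.pad, self.cin
        ho, wo = self._hw
        b = dout.shape[0]
        dm = dout.reshape(b * ho * wo, self.cout)
        self.grads = [(self._cols.T @ dm).astype(F)]
        if self.b is not None:
            self.grads.append(dm.sum(axis=0).astype(F))
        if k == 1:
            return (dm @ self.w.T).reshape(b, ho, wo, c)
        h, w = self._xshape[1:3]
        dcols_flat = self._buf("_dcols_buf", (b * ho * wo, k * k * c))
        np.matmul(dm, self.w.T, out=dcols_flat)
        dcols = dcols_flat.reshape(b, ho, wo, k * k, c)
        dxp = self._buf("_dxp_buf", (b, h + 2 * p, w + 2 * p, c))
        dxp[...] = 0
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + ho, j:j + wo, :] += dcols[:, :, :, i * k + j, :]
        return dxp[:, p:p + h, p:p + w, :] if p else dxp


class ConvTranspose2d(Layer):
    """4x4 transpose convolution, stride 2, pad 1: doubles spatial size."""

    K, S, P = 4, 2, 1

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.cin, self.cout = cin, cout
        k = self.K
        scale = np.sqrt(2.0 / (cin * k * k))
        self.w = rng.normal(0, scale, size=(cin, k * k * cout)).astype(F)
        self.b = np.zeros(cout, dtype=F)
        self.params = [self.w, self.b]

    def forward(self, x, train=True):
        b, h, w, cin = x.shape
        k, s, p = self.K, self.S, self.P
        cout = self.cout
        self._xm = np.ascontiguousarray(x).reshape(b * h * w, cin)
        self._inshape = x.shape
        cols_flat = Conv2d._buf(self, "_cols_buf", (b * h * w, k * k * cout))
        np.matmul(self._xm, self.w, out=cols_flat)
        cols = cols_flat.reshape(b, h, w, k * k, cout)
        ho, wo = s * h, s * w
        outp = Conv2d._buf(self, "_outp_buf", (b, ho + 2 * p, wo + 2 * p, cout))
        outp[...] = 0
        for i in range(k):
            for j in range(k):
                outp[:, i:i + s * h:s, j:j + s * w:s, :] += cols[:, :, :, i * k + j, :]
        return outp[:, p:p + ho, p:p + wo, :] + self.b

    def backward(self, dout):
        b, h, w, cin = self._inshape
        k, s, p = self.K, self.S, self.P
        cout = self.cout
        dp = np.pad(dout, ((0, 0), (p, p), (p, p), (0, 0)))
        win = Conv2d._buf(self, "_win_buf", (b, h, w, k * k, cout))
        for i in range(k):
            for j in range(k):
                win[:, :, :, i * k + j, :] = dp[:, i:i + s * h:s, j:j + s * w:s, :]
        winm = win.reshape(b * h * w, k * k * cout)
        dx = (winm @ self.w.T).reshape(b, h, w, cin)
        self.grads = [(self._xm.T @ winm).astype(F),
                      dout.sum(axis=(0, 1, 2)).astype(F)]
        return dx


class BatchNorm2d(Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=F)
        self.beta = np.zeros(c, dtype=F)
        self.params = [self.gamma, self.beta]
        self.running_mean = np.zeros(c, dtype=F)
        self.running_var = np.ones(c, dtype=F)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1, 2))
            var = x.var(axis=(0, 1, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(F)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(F)
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = (1.0 / np.sqrt(var + self.eps)).astype(F)
        self._xhat = ((x - mean) * self._istd).astype(F)
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        xhat, istd = self._xhat, self._istd
        self.grads = [(dout * xhat).sum(axis=(0, 1, 2)).astype(F),
                      dout.sum(axis=(0, 1, 2)).astype(F)]
        dxhat = dout * self.gamma
        if not self._train:
            return dxhat * istd
        t1 = dxhat - dxhat.mean(axis=(0, 1, 2), keepdims=True)
        t2 = xhat * (dxhat * xhat).mean(axis=(0, 1, 2), keepdims=True)
        return ((t1 - t2) * istd).astype(F)


class ReLU(Layer):
    def forward(self, x, train=True):
        self._m = x > 0
        return x * self._m

    def backward(self, dout):
        return dout * self._m


class MaxPool2(Layer):
    def forward(self, x, train=True):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = np.ascontiguousarray(xr).reshape(b, h // 2, w // 2, 4, c)
        self._idx = xr.argmax(axis=3)
        self._inshape = x.shape
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, dout):
        b, h, w, c = self._inshape
        dxr = np.zeros((b, h // 2, w // 2, 4, c), dtype=F)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :], dout[:, :, :, None, :], axis=3)
        dx = dxr.reshape(b, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(dx).reshape(b, h, w, c)


class Sigmoid(Layer):
    def forward(self, x, train=True):
        self.p = (1.0 / (1.0 + np.exp(-x))).astype(F)
        return self.p

    def backward(self, dout):
        return (dout * self.p * (1.0 - self.p)).astype(F)


class Sequential(Layer):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.iter_layers()
            else:
                yield layer


class Adam:
    """Adam with (coupled) L2 weight decay on the weight matrices."""

    def __init__(self, layers, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 weight_decay=0.0):
        self.layers = [l for l in layers if l.params]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [[np.zeros_like(p) for p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for p in l.params] for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for pi, (p, g) in enumerate(zip(layer.params, layer.grads)):
                if self.wd and p.ndim > 1:  # decay weights, not biases/BN
                    g = g + self.wd * p
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= self.b1; m += (1 - self.b1) * g
                v *= self.b2; v += (1 - self.b2) * g * g
                p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
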