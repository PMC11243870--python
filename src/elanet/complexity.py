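"""Analytic complexity accounting: trainable parameters and
multiply-accumulates (MACs), total and per component.

Counting conventions (the dominant-term convention of standard model
profilers, whose giga-scale numbers the published budgets match):

* a convolution contributes ``kh * kw * (Cin/groups) * Cout * Hout * Wout``
  MACs; its parameters are the kernel plus bias;
* a perceptron layer contributes ``fan_in * fan_out`` MACs;
* batch norm, pooling, activations, elementwise products and bilinear
  resampling contribute zero MACs (batch-norm affine pairs do count as
  parameters).

The published tables label the MAC column "FLOPs (G)"; this module
reports MACs and treats the two as aliases of the same count.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import ELANet

__all__ = ["ComplexityReport", "count_params", "count_macs", "report"]


@dataclass
class ComplexityReport:
    params_total: int
    macs_total: int
    input_size: tuple[int, int]
    per_module: list[tuple[str, int, int]]  # (path, params, macs)

    @property
    def params_millions(self) -> float:
        return round(self.params_total / 1e6, 3)

    @property
    def macs_giga(self) -> float:
        return round(self.macs_total / 1e9, 3)

    def pretty(self) -> str:
        width = max(len(p) for p, _, _ in self.per_module + [("total", 0, 0)])
        lines = [f"{'module':<{width}}  {'params':>10}  {'MACs':>14}"]
        for path, p, m in self.per_module:
            lines.append(f"{path:<{width}}  {p:>10,}  {m:>14,}")
        lines.append(
            f"{'total':<{width}}  {self.params_total:>10,}  {self.macs_total:>14,}"
        )
        lines.append(
            f"= {self.params_millions:.3f} M params, {self.macs_giga:.3f} G MACs "
            f"at {self.input_size[1]}x{self.input_size[0]} (WxH)"
        )
        return "\n".join(lines)


def count_params(net: ELANet) -> int:
    """Exact count of trainable scalars, from the per-layer closed forms."""
    return net.param_count()


def count_macs(net: ELANet, input_size: tuple[int, int] | None = None) -> int:
    """Analytic MAC count at ``input_size`` (height, width)."""
    hw = input_size or net.cfg.input_size
    if hw[0] % 8 or hw[1] % 8:
        raise ValueError(f"input_size must be divisible by 8, got {hw}")
    return sum(mod.macs(shape) for _, mod, shape in net.components(hw))


def report(net: ELANet, input_size: tuple[int, int] | None = None) -> ComplexityReport:
    hw = input_size or net.cfg.input_size
    per = [
        (path, mod.param_count(), mod.macs(shape))
        for path, mod, shape in net.components(hw)
    ]
    return ComplexityReport(
        params_total=count_params(net),
        macs_total=count_macs(net, hw),
        input_size=tuple(hw),
        per_module=per,
    )
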