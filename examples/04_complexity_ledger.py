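"""Operation-count comparison of the steady-state methods.

Exact arithmetic-operation tallies for the 49-state model: standard vs
banded Gaussian elimination, the block recursive procedure, and the
per-sweep cost of block Gauss-Seidel, with the crossover iteration
counts that decide which method is cheaper.
"""

from gjgate.complexity import (
    banded_ge_ops,
    bgs_sweep_ops,
    efficiency_threshold,
    recursive_ops,
    standard_ge_ops,
)

n, m = 49, 15
rec = recursive_ops(7)
sweep = bgs_sweep_ops("two12")

print(f"49-state model (bandwidth m = {m}):")
print(f"  standard Gaussian elimination : {standard_ge_ops(n):7d} ops")
print(f"  banded Gaussian elimination   : {banded_ge_ops(n, m):7d} ops")
print(f"  block recursive procedure     : {rec.total_ops:7d} ops")
print(f"  block Gauss-Seidel, per sweep : {sweep.total_ops:7d} ops")

print("\nblock Gauss-Seidel is cheaper than")
print(f"  standard GE below {efficiency_threshold(standard_ge_ops(n), sweep.total_ops, 'ceil')} outer iterations")
print(f"  the recursion at  {efficiency_threshold(rec.total_ops, sweep.total_ops, 'floor')} or fewer outer iterations")
print(f"\nrecursive vs standard GE saving: "
      f"{standard_ge_ops(n) / rec.total_ops:.1f}-fold")
print("\n28-state model: per-sweep cost "
      f"{bgs_sweep_ops('three6').total_ops}, cheaper than standard GE below "
      f"{efficiency_threshold(standard_ge_ops(28), 196, 'floor')} iterations")
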