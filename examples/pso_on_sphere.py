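"""Swarm search on a known objective inside the hyperparameter bounds.

A sphere centred inside the five-dimensional search space (three unit
counts, dropout rate, batch size) stands in for the validation loss; the
swarm should drive the global best towards the centre, and the global-best
trace never increases.
"""

from affectlstm import PSOConfig, SearchSpace, optimize

m = {"units1": 57.0, "units2": 123.0, "dense_units": 88.0,
     "dropout_rate": 0.47, "batch_size": 101.0}
space = SearchSpace.default()
scale = {d.name: d.range for d in space.dims}
fitness = lambda d: sum(((d[k] - m[k]) / scale[k]) ** 2 for k in m)

result = optimize(fitness, space,
                  PSOConfig(particles=15, iterations=10, seed=0))
print("global best per iteration (never increases):")
for it, loss in result.trace:
    print(f"  iteration {it:2d}: {loss:.6f}")
print(f"best decoded hyperparameters: {result.best_params}")
print(f"fitness evaluations: {len(result.log)} "
      f"({result.fitness_calls} actual trainings, rest cache hits)")
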