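"""Compare the baseline and improved Archimedes optimizers on benchmark functions.

Runs both optimizers on the six-hump camel (2-D, optimum -1.0316) and the
30-D Griewank function (optimum 0) for ten seeded repetitions each and
prints the Best/Mean/Worst/Std table. The improved variant's chaotic
initialization and elite mutation typically tighten both the best value and
the spread; on Griewank it can reach an exact 0.0 in double precision.
"""

from iaoadbn import format_table, run_benchmark_matrix

report = run_benchmark_matrix(
    algorithms=["aoa", "iaoa"],
    functions=["F12", "F8"],
    runs=10,
    master_seed=1,
    population_size=30,
    max_iterations=500,
)
print(format_table(report, "tab5"))
print("Rows: aggregate statistics over 10 independent runs; columns: functions.")
print("F12 cells near -1.03E+00 and F8 cells at 0.00E+00 reproduce the known optima.")
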