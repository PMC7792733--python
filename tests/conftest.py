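import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gls_pairs():
    """Packaged 48-subject paired GLS fixture, values as printed."""
    from strainpost import load_gls_validation_pairs

    return load_gls_validation_pairs()


@pytest.fixture(scope="session")
def noiseless_study():
    """Deterministic noise-free 18-segment synthetic study."""
    from strainpost import SyntheticStudySpec, generate_strain_cycle

    spec = SyntheticStudySpec()
    trace, ecg, events = generate_strain_cycle(spec)
    return spec, trace, ecg, events


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# independent statistical oracle: R's stats package, run once in batch over
# random paired samples (normal and skewed, to exercise both gates)

N_ORACLE_SAMPLES = 100

_R_BATTERY = """
args <- commandArgs(TRUE)
d <- read.table(args[1], header = TRUE)
lines <- c()
for (id in unique(d$id)) {
  s <- d[d$id == id, ]
  a <- s$a; b <- s$b; dd <- a - b
  swa <- shapiro.test(a); swb <- shapiro.test(b); swd <- shapiro.test(dd)
  if (swa$p.value > 0.05 && swb$p.value > 0.05) {
    meth <- "pearson"; r <- cor(a, b)
  } else {
    meth <- "spearman"; r <- cor(a, b, method = "spearman")
  }
  if (swd$p.value > 0.05) {
    tm <- "t_paired"
    p <- t.test(a, b, paired = TRUE)$p.value
  } else {
    tm <- "wilcoxon"
    ex <- sum(dd != 0) <= 25
    p <- wilcox.test(a, b, paired = TRUE, exact = ex, correct = TRUE)$p.value
  }
  lines <- c(lines, sprintf("%s,%.12g,%.12g,%s,%.12g,%s,%.12g",
             id, swa$statistic, swa$p.value, meth, r, tm, p))
}
writeLines(lines, args[2])
"""


@pytest.fixture(scope="session")
def r_battery_oracle(tmp_path_factory):
    """Gated battery computed by R over 100 random paired samples.

    Returns ``(samples, results)``: per sample id the (a, b) arrays and R's
    Shapiro-Wilk W/p (on a), gated correlation method and coefficient, and
    gated location-test method and p-value.
    """
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not found; the oracle cross-check cannot run")
    tmp = tmp_path_factory.mktemp("roracle")
    rng = np.random.default_rng(20240901)
    samples = {}
    rows = ["id\ta\tb"]
    for i in range(N_ORACLE_SAMPLES):
        n = int(rng.integers(10, 49))
        if i % 2 == 0:
            a = rng.normal(-15, 4, n)
            b = a - 0.2 + rng.normal(0, 0.7, n)
        else:  # skewed marginals / skewed differences
            a = -rng.lognormal(2.2, 0.5, n)
            b = a - 0.2 + rng.lognormal(0, 0.8, n) - 1.0
        samples[str(i)] = (a, b)
        rows += [f"{i}\t{x:.12g}\t{y:.12g}" for x, y in zip(a, b)]
    data = tmp / "samples.tsv"
    data.write_text("\n".join(rows) + "\n")
    script = tmp / "oracle.R"
    script.write_text(_R_BATTERY)
    out = tmp / "out.csv"
    subprocess.run(
        ["Rscript", "--vanilla", str(script), str(data), str(out)],
        check=True, capture_output=True, text=True, timeout=300,
    )
    results = {}
    for line in out.read_text().splitlines():
        sid, w, wp, meth, r, tm, p = line.split(",")
        results[sid] = dict(
            sw_w=float(w), sw_p=float(wp), corr_method=meth, r=float(r),
            test_method=tm, p=float(p),
        )
    return samples, results
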