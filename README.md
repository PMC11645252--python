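# qmim — purchase mimicry in checkout queues

`qmim` is a matched observational-study pipeline for quantifying **food-choice
mimicry**: when the person directly ahead of you in a cafeteria checkout queue
buys a dessert, how much more likely are you to buy one too?  It takes raw
timestamped point-of-sale logs (one row per badge transaction: user, shop,
register, time, item codes), mines them for **dyads** — adjacent purchases by
two people at the same register within 5 minutes with nobody in between — and
estimates the causal effect of the queue partner's purchase on the focal
person's purchase with a matched-pair design.

## The design in brief

Peer similarity in purchases is confounded two ways: **homophily** (friends
who queue together have similar tastes) and **shared context** (both face the
same shop, day, menu and popularity fluctuations).  Under the standard DAG
for social influence in pairs, the backdoor adjustment set is the partner's
identity plus the common environmental factors.  The pipeline realises it by
matching: for each focus item *i*, a **treated dyad** (partner bought *i*) is
paired with a **control dyad** with the *same partner*, *same shop*, *same
meal period*, where *i* was available and equally popular (within a 10%
caliper on the stratum-level popularity, the fraction of that shop/day/period's
transactions containing *i*).  Only user pairs observed adjacent ≥ 10 times
are analysed, so the same partner recurs in both arms.

Across matched pairs, with $Y_a(t)$, $Y_b(t)$ the partner's and focal
person's purchased item sets, the headline estimands are

$$\mathrm{RD}_i = p(i \in Y_b(t) \mid i \in Y_a(t)) - p(i \in Y_b(t) \mid i \notin Y_a(t)),
\qquad
\mathrm{RR}_i = \frac{p(i \in Y_b(t) \mid i \in Y_a(t))}{p(i \in Y_b(t) \mid i \notin Y_a(t))}$$

computed from the paired 2×2 table (`n11`, `n10`, `n01`, `n00`) as
RD = (n10 − n01)/n and RR = (n11+n10)/(n11+n01), with percentile-bootstrap
95% CIs, a McNemar paired χ² test, and three robustness analyses:

* **randomized-partner baseline** — re-estimate after replacing each partner
  with a random same-shop/day/period transactor; what survives is context,
  not queue influence;
* **dose–response** — RD by 10-second queue-lag bins with a weighted
  least-squares trend (a causal queue effect should fade with distance);
* **Rosenbaum sensitivity** — the hidden-bias odds ratio Γ at which the
  paired sign test loses significance, with the amplification
  Γ = (ΛΔ+1)/(Λ+Δ) into confounder→treatment (Λ) and confounder→outcome (Δ)
  components.

Because real campus transaction logs are private, the package ships a
synthetic generator (`qmim.synthgen`) that emulates the data-generating
process — eating profiles, homophilous co-queueing ties, day×shop popularity
shocks, anchor+addition purchases over three meal periods, and a planted
additive mimicry effect δ·e^(−lag/τ) — and records every decision's
counterfactual purchase probabilities, so the pipeline can be validated
against a known ground truth (`rd*`).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic data
(300 users × 60 days, planted δ = 0.15 with no lag decay):

```sh
python analysis/01_simulate.py
python analysis/02_extract_dyads.py
python analysis/03_match_and_estimate.py
python analysis/04_robustness.py
python analysis/05_subgroups.py
```

which prints, among other things:

```
wrote 24352 transactions; ground-truth rd* = 0.1500 (clipping 0.00%)
10681 dyads, 9734 after the >=10 filter; mean lag 13.9s (SD 14.1), 98.6% under a minute
pooled over additions: RD 14.05% [12.25%, 15.79%], RR 1.81, McNemar chi2 235.0 (p=4.91e-53) over 4262 pairs
matched RD 14.05% vs randomized baseline -0.53%
dose-response slope -0.00396 RD/s (p=1.26e-04)
sensitivity Gamma* = 2.09 at alpha 0.05
```

Read: the matched estimate (14.05%, CI covering the planted ground truth of
15 percentage points) survives matching, collapses to ≈0 once queue order is
randomized, and — in a companion run with τ = 30 s — decays with queue lag;
an unobserved confounder would need to more than double the within-pair
treatment odds (Γ* ≈ 2.1) to explain it away.  The same flow is scriptable
from one YAML config via `qmim run --config study.yaml`, or stage by stage
with `qmim simulate / validate / dyads / match / estimate / robustness`.

The library is importable directly:

```python
from qmim import effects
counts = effects.ContingencyCounts(n11=3042, n10=12119, n01=5221, n00=28111)
est = effects.estimate(counts, seed=0)
print(f"RD {est.rd:.2%}, RR {est.rr:.2f}")   # RD 14.22%, RR 1.83
```

## Layout

```
src/qmim/          library: transactions, dyads, matching, effects,
                   robustness, synthgen, pipeline, cli
analysis/          numbered narrative drivers (write to results/, scratch/)
tests/             pytest suite, incl. end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameter choices, limitations
```
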