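# maizetrial

Analysis pipeline for multi-year field trials that compare summer maize
(*Zea mays* L.) hybrids of different growth duration — for agronomists and
crop physiologists who want the full chain from raw trial tables to the
physiological bookkeeping that explains a yield difference:

- **Thermal time.** Daily growing degree days `GDD = max(0, (Tmax+Tmin)/2 − Tbase)`
  with `Tbase = 10 °C`, accumulated over the sowing→silking (R1) and
  silking→maturity (R6) windows of each year × hybrid.
- **Canopy dynamics.** Post-silking leaf area index follows a Gaussian,
  `LAI(t) = A·exp(−(t−B)²/2C²)`; the *duration of higher LAI* is
  `DLAI = C·√(2 ln 2)`, the time to fall from the maximum to half of it.
  Ear-leaf net photosynthesis declines linearly, `Pn = a − b·t`; with `Pi`
  the initial post-silking Pn, the *active photosynthesis duration* is
  `APD = Pi/(2b)`.
- **Dry-matter partitioning.** Pre/post-silking accumulation shares
  (PrSDMAR/PoSDMAR), organ remobilization `DMR = m(R1) − m(R6)` and
  efficiency `DMRE = 100·DMR/m(R1)`, the ¹³C-pulse-label correction that
  converts leaf+stalk DMR into its grain contribution
  `DMRC = 100·(DMR_leaf⁺ + DMR_stalk⁺)·f_grain / grain(R6)`, harvest index
  `HI = grain/total at R6`, sink capacity, grain/leaf ratio and yield per GDD.
- **Trial statistics.** Balanced two-way ANOVA (year, hybrid, year×hybrid),
  LSD mean-separation letters at α = 0.05, Pearson correlation and OLS
  regression, and the per-year percent/paired difference ranges trial reports
  quote.
- **Synthetic trials.** A generator that emulates a 5-year, 2-hybrid,
  3-replicate trial with known closed-form ground truth for every metric, so
  the whole pipeline is testable without field data.

## Worked example

```bash
maizetrial generate --seed 7 --out demo      # synthetic trial, CSV tables
maizetrial analyze --in demo --out out       # full report bundle
```

`out/` then holds `yield_components.csv`, `stage_gdd.csv`, `partitioning.csv`,
`remobilization.csv`, `dmrc.csv`, `canopy_fits.csv`, `grain_leaf_hi.csv`
(each with LSD letters and a two-way ANOVA footer), `correlations.csv`, and
full-precision copies under `out/machine/`. For seed 7 the first rows of
`grain_leaf_hi.csv` are

```
year,hybrid,sink_capacity,sink_capacity_letter,lai_r1,lai_r1_letter,grain_leaf,grain_leaf_letter,hi,hi_letter
2017,DH518,1215.7,a,4.42,b,0.275,a,0.58,a
2017,DH605,1275.1,a,5.11,a,0.25,b,0.554,b
```

— the early hybrid (DH518-like) has the higher harvest index and grain/leaf
ratio (letters `a` vs `b`: significantly different within the year at the 5%
LSD), while the mid-late hybrid carries the larger canopy. `canopy_fits.csv`
shows why:

```
year,hybrid,A,B,C,R2,dlai,a,b,r,pi,apd
2017,DH518,4.52,6.58,43.22,0.988,50.89,47.12,0.54,0.988,47.34,44.18
2017,DH605,5.09,4.2,51.15,0.987,60.22,49.08,0.44,0.991,49.31,55.98
```

The mid-late hybrid holds a high LAI for ~9 days longer (DLAI 60.2 vs 50.9)
and keeps photosynthesis active ~12 days longer (APD 56.0 vs 44.2) — the
canopy-persistence advantage that drives its extra post-silking dry matter.
The ANOVA footer of `yield_components.csv` reports the hybrid effect on
yield as `F=16.354 p=0.001 **`, and `correlations.csv` shows the strong
negative association between pre-silking duration and harvest index
(`r = −0.896` in this realization).

The same computations are available as a library:

```python
from maizetrial import generate_trial
from maizetrial.cli_report import analyze_trial

ds, truth = generate_trial(seed=7)
bundle = analyze_trial(ds)
bundle.tables["canopy_fits"]
```

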