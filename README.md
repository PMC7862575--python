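# likertcal

Detection and correction of non-equidistant Likert-scale metrics for
multi-scale survey instruments whose scales lie on a known valence/arousal
circumplex (the eight soundscape perceptual attributes: pleasant, annoying,
vibrant, monotonous, calm, chaotic, eventful, uneventful; five-point scales).

The core idea: collapse responses per site into disagreement/neutral/agreement
percentage shares, correlate the 24 grouped variables across sites, keep the
strongly correlated, significant pairs, and propagate a fixed anchor value
(pleasant-disagreement = −1) through a maximum-|r| spanning forest of
directional regression slopes. The propagated pole extents, barycenter and
neutral side yield five corrected values per scale, which replace 1–5 when
projecting responses onto the circumplex.

## Modules

| module | contents |
|---|---|
| `likertcal.io` | survey CSV reading/validation, category recoding (`CodingConfig`), correction-table JSON I/O |
| `likertcal.attributes` | canonical attribute set, circumplex angles, polarities, the 24 grouped-category nodes |
| `likertcal.projection` | ISO circumplex projection, per-site mean profiles, paired-attribute mean fits |
| `likertcal.association` | grouped percentages, 24×24 r/p/slope matrices, edge admissibility |
| `likertcal.correction` | anchored slope propagation, neutral sign, corrected category values, corrected projection |
| `likertcal.simulation` | uniform-response simulation plus an exact 5⁶ enumeration oracle for projected tails |
| `likertcal.synthetic` | latent-threshold multi-site survey generator with known ground truth; parameter-recovery scoring |
| `likertcal.report` / `likertcal.cli` | full-pipeline report bundle and the `likertcal` command |

## CLI

```sh
likertcal synth --sites 30 --respondents 100 --seed 1 --out synth.csv
likertcal project synth.csv --out coords.csv           # ISO projection
likertcal associations synth.csv --outdir tables/      # r/p/slope matrices
likertcal derive synth.csv --out ct.json --r-min 0.5   # correction table
likertcal apply synth.csv ct.json --out corrected.csv  # corrected projection
likertcal simulate --n 30000 --seed 1 --tail 0.6 --out summary.json
likertcal report synth.csv --outdir bundle/ --r-min 0.5
```

`derive`/`report` accept `--config cfg.yaml` mirroring all flags (explicit
flags win), `--anchor pleasant:D:-1`, `--mode proportional|angle`,
`--alpha`, `--min-sites`. Note: on synthetic ring-geometry data the default
`--r-min 0.7` usually leaves the association graph disconnected (a hard
error by design); lower it, e.g. `--r-min 0.5`.

## Survey CSV schema

```
site_id,respondent_id,pleasant,annoying,vibrant,monotonous,calm,chaotic,eventful,uneventful
```

Responses are integers 1–5 (canonically 5 = strongly agree; use
`--coding agree_low` for reversed inputs, or a label map via the API).
Extra columns (demographics) are ignored.

## Caveats

- Edge admissibility applies no multiple-testing correction (mirroring the
  source analysis); p-values are per-edge.
- The derivation identifies dilation/compression only, never shifts between
  scales.
- Corrected-coordinate normalization is per dimension (valence and arousal
  normalized independently).
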