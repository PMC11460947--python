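# seedwind

Wind-dispersal efficiency modelling for winged seeds and ovules, built
around the earliest known winged diaspores: the Famennian (Late
Devonian) ovule genera with three integumentary wings (*Alasemenia
tria*) and four (*Guazia dongzhiensis*, *Warsteinia*). The package is
aimed at palaeobotanists and biomechanists who want to compare the
anemochory potential of diaspores that differ in wing number, and at
anyone who needs a clean, tested implementation of the windward-area
autorotation model.

## The model

An ovule with `n` wings attached radially and symmetrically around its
long axis autorotates as it falls. At rotation angle `θ` (between the
airflow and a reference wing, in the rotation plane) the wings present
a combined projected — *windward* — area to the flow. With `S_wing` the
maximum windward area of one wing, the body shadows all but the two
best-presented wings, so

```
S(θ) = S_wing · ( two largest values of |sin(azimuth)| ),   azimuths = θ + 2πk/n
```

(for a single wing, just `S_wing·|sin θ|`). This reproduces the
per-count closed forms

| n | S(θ) | range of S | D = ∫₀^{2π} S dθ | Er | stability min S / max S |
|---|------|------------|------------------|-----|--------------------------|
| 1 | `S_wing·|sin θ|` | [0, S_wing] | `4·S_wing` | 63.66 % | 0 |
| 2 | `2·S_wing·|sin θ|` | [0, 2·S_wing] | `8·S_wing` | 63.66 % | 0 |
| 3 | `√3·S_wing·cos(π/3 − θ)` | [1.5, √3]·S_wing | `6√3·S_wing` | 82.70 % | √3/2 ≈ 0.866 |
| 4 | `2·S_wing·max(|sin θ|, |cos θ|)` | [√2, 2]·S_wing | `8√2·S_wing` | 90.03 % | √2/2 ≈ 0.707 |

`D` is the windward area accumulated over one rotation; the relative
efficiency `Er = D / D_control` compares it with a non-rotating control
that keeps its wings facing the wind (`D_control = 2π·S_wing·min(n,2)`).
Four wings are slightly more efficient than three, but three wings give
the most *stable* windward area over the cycle — the quantitative basis
for regarding three-winged diaspores as best adapted to steady
autorotation. Beyond four wings the projection rule is an extrapolation
and is flagged as such.

Companion modules provide the aerodynamic side relations (thrust
`F = c·ρ·v²·S`, terminal-velocity scaling `v_ter ∝ √(w/A_W)` with wing
loading `w/A_W`, Reynolds-number regime check for the 10³–10⁴ band),
machine-checkable morphometric diagnoses of the three genera with a
specimen validator, and a seeded generator of synthetic specimen
populations.

## Worked example

```python
>>> from seedwind import DiasporeRotor, relative_efficiency, windward_stability
>>> res = relative_efficiency(DiasporeRotor(n=3, swing=1.0))
>>> round(res.d_rotating, 4), round(res.er_percent, 2)
(10.3923, 82.7)
>>> round(windward_stability(DiasporeRotor(n=3, swing=1.0)), 4)
0.866
```

`10.3923` is `6√3`, the windward area (in units of `S_wing·radian`)
accumulated over one rotation by a three-winged diaspore; it reaches
82.70 % of the facing-wind control's accumulation, and its windward
area never drops below 86.6 % of its maximum — the steadiest of all
wing counts.

The same numbers from the command line, plus the full summary table and
the three-genus comparison:

```sh
seedwind efficiency --n 3
# n=3  D_rotating=10.3923*Swing  D_control=12.5664*Swing  Er=82.70%  stability=0.8660  (closed_form)
seedwind table --n-max 4 --format markdown
seedwind compare-taxa
seedwind specimens simulate --output pop.csv --count 100 --seed 42
seedwind specimens validate pop.csv        # -> 100/100 conforming to alasemenia_tria
```

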