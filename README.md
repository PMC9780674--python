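# rsmferm

Sequential design-of-experiments analysis for fermentation-medium
optimization: **Plackett–Burman screening → path of steepest ascent →
Box–Behnken response-surface modelling → constrained optimum**.

The package is for bioprocess scientists who optimize culture media (or any
multi-factor process) with the classical three-stage response-surface
workflow and want the whole analysis — model fits, ANOVA with lack-of-fit,
effect ranking, canonical analysis, optimum search — as reproducible,
scriptable code instead of point-and-click statistics software.

## The models

**Stage 1 — screening.** A two-level Plackett–Burman design estimates main
effects of k factors in n runs (n = 8, 12, 16, 20). The first-order model

    Y = β₀ + Σᵢ βᵢxᵢ

is fitted by OLS on coded levels xᵢ ∈ {−1, +1}; on the orthogonal design
the coefficients equal the contrast estimates Σ(xᵢy)/n and each factor's
single-df sum of squares is n·βᵢ². Factors with p < α (F test against the
regression residual) are carried forward, with the sign of βᵢ giving the
direction to move.

**Stage 2 — steepest ascent.** A short series of runs steps the selected
factors from a base point; the maximal-response step becomes the center of
the follow-up design. Both the textbook coefficient-sign path and an
explicit user-supplied grid are supported.

**Stage 3 — response surface.** A three-level Box–Behnken design (12 edge
runs + replicated centers) supports the full quadratic

    Y = β₀ + Σβᵢxᵢ + Σᵢ<ⱼ βᵢⱼxᵢxⱼ + Σβᵢᵢxᵢ²

The ANOVA reports Type III single-df term sums of squares, splits the
residual into lack of fit and pure error (from the center replicates), and
gives R², adjusted R² and the coefficient of variation. Canonical analysis
classifies the stationary point (−B⁻¹b, Hessian eigenvalue signs), and the
constrained maximum over the coded cube is found by a dense grid scan plus
a bounded local polish.

The fitting stages are scikit-learn-style estimators
(`FirstOrderScreening`, `QuadraticResponseSurface`) with `fit`/`predict`
and trailing-underscore attributes, so they compose with sklearn tooling;
`fit_first_order`/`fit_quadratic` are thin wrappers taking the package's
`DesignMatrix`/`ResponseSet` containers.

## Worked example

The package ships the complete data of a published medium-optimization
study for mycelial soluble protein of *Ophiocordyceps sinensis* (six medium
components screened in 12 runs, a 5-step ascent, a 17-run Box–Behnken
design over beef broth, peptone and glucose):

```python
import rsmferm as rf
from rsmferm import datasets

# stage 1: screen six medium components in 12 runs
design, responses = datasets.pb_screen()
screen = rf.fit_first_order(design, responses)
print(round(screen.intercept_, 2), dict(zip(screen.feature_names_in_, screen.coef_.round(4))))
# 1.64 {'beef_broth': -0.0608, 'peptone': 0.0925, 'yeast_extract': -0.0142,
#       'glucose': -0.0808, 'KH2PO4': -0.0025, 'MgSO4': 0.0158}
sel = screen.select(alpha=0.05)
print(list(sel.index[sel.selected]))   # ['beef_broth', 'peptone', 'glucose']
print(round(screen.r2_adj_, 4))        # 0.8853

# stage 2: pick the response-surface center from the ascent path
path = datasets.ascent_path()
center, _ = rf.select_center(path)
print(center)                          # {'beef_broth': 30.0, 'peptone': 0.3, 'glucose': 2.0}

# stage 3: quadratic surface over the three selected factors
bbd, resp = datasets.bbd_experiment()
quad = rf.fit_quadratic(bbd, resp)
print(round(quad.intercept_, 2), round(quad.r2_, 3), round(quad.cv_percent_, 1))
# 2.07 0.988 1.7
print(quad.anova_.loc["glucose", "F"].round(2))        # 237.18
print(quad.rank_effects()["linear"])   # ['glucose', 'peptone', 'beef_broth']

sp = rf.stationary_point(quad)
print(sp.nature)                       # 'saddle'
opt = rf.constrained_max(quad, factors=bbd.factors)
print(opt.constrained_coded.round(3), round(opt.predicted_response, 3))
# [-0.125 -1.     0.176] 2.158
print(round(float(quad.predict([[-1, -1, 0]])[0]), 2))  # 2.11
```

The screening fit flags beef broth (−), peptone (+) and glucose (−) as the
significant components; the ascent stage centers the surface design at
(30 %, 0.3 %, 2 %); the quadratic fit explains 98.8 % of the response
variation with a non-significant lack of fit, and its strongest effects are
glucose and glucose². The fitted surface is a saddle, so the optimum lies
on the boundary of the explored region: the model predicts 2.11 % protein
at the low-beef-broth, low-peptone edge (20 %, 0.10 %, 2 % in actual
units), and its unconstrained-within-cube maximum (≈2.16 %) sits on the
same low-peptone face. Both numbers are reported side by side by the
optimum stage.

A command-line interface mirrors the library
(`rsmferm design|validate|screen|rsm|ascent-select|optimize|surface|simulate|run`);
`rsmferm run --synthetic` exercises the full pipeline on simulated data
from `rsmferm.simulate`.

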