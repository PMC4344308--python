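"""Model/Results interface for the sector-versus-conservation analysis.

``SCA`` bundles an alignment with the analysis options (gap threshold,
background, gap handling, clamp, sector fraction); ``fit()`` runs the
pipeline — gap-column filtering, frequency model, relative-entropy
conservation, projection, SCA matrix, eigendecomposition, sector
extraction — and returns an ``SCAResults`` holding every intermediate
quantity along with comparison and plotting helpers.

Example
-------
>>> from seqsector import SCA, simulate
>>> spec = simulate.GeneratorSpec(kind="independent", N=500, n=100, seed=0,
...                               conservation_profile=0.6)
>>> res = SCA(simulate.sample_independent_alignment(spec)).fit()
>>> len(res.sector.positions)
25
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from . import backgrounds
from .alignment import Alignment, filter_gap_columns, map_columns_to_reference
from .compare import (
    MutationalDataset,
    contingency,
    fisher_one_tailed,
    mannwhitney_effects,
    sweep_sector_size,
)
from .conservation import (
    ConservationProfile,
    FrequencyModel,
    conservation_profile,
    frequency_model,
    top_conserved_set,
)
from .sca import (
    SCAMatrix,
    Sector,
    SpectralResult,
    extract_sector,
    positional_weights,
    project_alignment,
    sca_matrix,
    spectral,
    topvec_diag_correlation,
)


class SCA:
    """Projection-method statistical coupling analysis of an alignment.

    Parameters
    ----------
    alignment
        The input alignment (gap columns are filtered in ``fit``).
    background
        Background frequencies over the 20 amino acids; defaults to the
        shipped database-average table.
    gap_threshold
        Columns with gap fraction at or above this are removed (default
        0.4).  ``None`` disables filtering.
    gap_mode
        How the background treats gaps: ``average_gap`` (default) or
        ``ignore_gap``.
    clamp
        Frequency clamping bound for the positional weights.
    sector_fraction
        Fraction of columns in the sector (default 0.25).
    """

    def __init__(
        self,
        alignment: Alignment,
        background: np.ndarray | None = None,
        gap_threshold: float | None = 0.4,
        gap_mode: str = "average_gap",
        clamp: float = 0.001,
        sector_fraction: float = 0.25,
    ) -> None:
        self.alignment = alignment
        self.background = (
            backgrounds.default_background() if background is None else np.asarray(background, float)
        )
        self.gap_threshold = gap_threshold
        self.gap_mode = gap_mode
        self.clamp = clamp
        self.sector_fraction = sector_fraction

    @classmethod
    def from_fasta(cls, path, reference_id: str | None = None, **kwargs) -> "SCA":
        from .alignment import read_fasta_alignment

        return cls(read_fasta_alignment(path, reference_id), **kwargs)

    def fit(self, n_modes: int | None = None) -> "SCAResults":
        aln = self.alignment
        if self.gap_threshold is not None:
            aln = filter_gap_columns(aln, self.gap_threshold)
        freq = frequency_model(aln, self.background, self.gap_mode)
        D = conservation_profile(freq)
        phi = positional_weights(freq, self.clamp)
        projected = project_alignment(aln, freq, phi)
        C = sca_matrix(projected)
        spec = spectral(C, n_modes)
        sector = extract_sector(spec, C.n, self.sector_fraction)
        return SCAResults(
            model=self,
            filtered_alignment=aln,
            frequencies=freq,
            conservation=D,
            sca=C,
            spectrum=spec,
            sector=sector,
        )


@dataclasses.dataclass
class SCAResults:
    """Fitted SCA pipeline: conservation, coupling matrix, spectrum, sector."""

    model: SCA
    filtered_alignment: Alignment
    frequencies: FrequencyModel
    conservation: ConservationProfile
    sca: SCAMatrix
    spectrum: SpectralResult
    sector: Sector

    # -- convenience accessors -------------------------------------------
    @property
    def n_columns(self) -> int:
        return self.sca.n

    @property
    def sector_columns(self) -> list[int]:
        return list(self.sector.positions)

    def column_to_reference(self) -> list[int | None]:
        """Map filtered columns to 1-based reference residue numbers."""
        ref = self.filtered_alignment.reference_id
        if ref is None:
            raise ValueError("alignment has no reference_id")
        return map_columns_to_reference(self.filtered_alignment, ref)

    def sector_residues(self) -> list[int]:
        """Sector positions as 1-based reference residue numbers."""
        mapping = self.column_to_reference()
        return sorted(
            int(mapping[c]) for c in self.sector.positions if mapping[c] is not None
        )

    def conserved_columns(self, k: int | None = None) -> list[int]:
        if k is None:
            k = len(self.sector.positions)
        return top_conserved_set(self.conservation, k)

    def diagnostics(self) -> dict:
        """Fig-1-style correlations of the top eigenvector with
        sqrt(diagonal) and with conservation."""
        return topvec_diag_correlation(self.sca, self.spectrum, self.conservation)

    # -- comparison battery ----------------------------------------------
    def compare_with_conservation(
        self, data: MutationalDataset, use_reference_numbering: bool = False
    ) -> dict:
        """The head-to-head statistical comparison on a mutational dataset.

        Builds the sector and equally sized conserved-set contingency
        tables, the one-tailed Fisher p for each, the chi-squared
        homogeneity p between them, and the two-sided Mann-Whitney p on
        the effect distributions.
        """
        from .compare import chi2_compare_tables

        mapping = (
            self.column_to_reference() if use_reference_numbering else None
        )

        def to_pos(cols: Sequence[int]) -> list[int]:
            if mapping is None:
                return [c + 1 for c in cols]
            return [int(mapping[c]) for c in cols if mapping[c] is not None]

        scored = set(int(p) for p in data.position)
        sector_pos = [p for p in to_pos(self.sector.positions) if p in scored]
        cons_pos = [
            p for p in to_pos(self.conserved_columns()) if p in scored
        ]
        out = {
            "sector_positions": sector_pos,
            "conserved_positions": cons_pos,
            "overlap": len(set(sector_pos) & set(cons_pos))
            / max(len(sector_pos), 1),
            "p_mannwhitney": mannwhitney_effects(data, sector_pos, cons_pos),
        }
        if data.functional is not None:
            t_sector = contingency(sector_pos, data)
            t_cons = contingency(cons_pos, data)
            out.update(
                sector_table=t_sector,
                conserved_table=t_cons,
                p_fisher_sector=fisher_one_tailed(t_sector),
                p_fisher_conserved=fisher_one_tailed(t_cons),
                p_chi2_tables=chi2_compare_tables(t_sector, t_cons),
            )
        return out

    def sweep(self, data: MutationalDataset, sizes: Sequence[int]) -> pd.DataFrame:
        return sweep_sector_size(
            self.spectrum, self.conservation, data, sizes
        )

    # -- reporting --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Per-column table: conservation, sqrt(diagonal), top-eigenvector
        loading, sector membership."""
        in_sector = np.zeros(self.n_columns, dtype=bool)
        in_sector[self.sector.positions] = True
        return pd.DataFrame(
            {
                "column": np.arange(self.n_columns),
                "conservation": self.conservation.D,
                "sqrt_diag": np.sqrt(self.sca.diag),
                "top_loading": self.spectrum.top_eigenvector,
                "in_sector": in_sector,
            }
        )

    def summary(self) -> str:
        diag = self.diagnostics()
        aln = self.filtered_alignment
        lines = [
            "Statistical coupling analysis (projection method)",
            "=" * 49,
            f"sequences (N):            {aln.n_sequences}",
            f"columns after filtering:  {aln.n_columns}",
            f"top eigenvalue:           {self.spectrum.top_eigenvalue:.4f}",
            f"second eigenvalue:        {self.spectrum.eigenvalues[1]:.4f}"
            if len(self.spectrum.eigenvalues) > 1
            else "",
            f"sector size ({self.sector.fraction:.0%} rule):   "
            f"{len(self.sector.positions)}",
            f"r(v_top, sqrt diag):      {diag['r_sqrt_diag']:.4f}"
            if diag["r_sqrt_diag"] is not None
            else "r(v_top, sqrt diag):      undefined",
            f"r(v_top, conservation):   {diag['r_conservation']:.4f}"
            if diag["r_conservation"] is not None
            else "r(v_top, conservation):   undefined",
        ]
        return "\n".join(line for line in lines if line)

    def plot_diagnostics(self, path=None):
        """Scatter of top-eigenvector loadings against sqrt(diagonal) and
        conservation; saves to ``path`` when given, else returns the
        figure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        diag = self.diagnostics()
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(diag["sqrt_diag"], diag["v_top"], s=8)
        axes[0].set_xlabel("sqrt(diagonal of SCA matrix)")
        axes[0].set_ylabel("top-eigenvector component")
        axes[1].scatter(diag["conservation"], diag["v_top"], s=8)
        axes[1].set_xlabel("conservation (nats)")
        axes[1].set_ylabel("top-eigenvector component")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
            return None
        return fig
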