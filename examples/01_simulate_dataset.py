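"""Generate a synthetic Red-List-style trait dataset and inspect it.

Draws 600 species in nested taxonomic groups with 30 categorical
attributes in three availability tiers, decline/rarity labels from a
planted logistic model, and MCAR missingness — then prints the planted
ground truth the rest of the pipeline should be able to recover.
"""

from redlistrf import SyntheticConfig, generate

table, occupancy, truth = generate(SyntheticConfig(seed=1))

print(f"species:            {table.n_species}")
print(f"attributes:         {table.n_attributes}")
print(f"missing cells:      {table.missing_mask.mean():.1%}")
print(f"decline prevalence: {truth.realized_prevalence:.3f}")
print(f"rarity prevalence:  {truth.realized_rarity_prevalence:.3f}")
print(f"planted informative attributes: {truth.informative}")
print(f"Bayes-optimal accuracy (Monte Carlo): {truth.bayes_accuracy:.3f}")
# The Bayes accuracy is the ceiling any classifier can reach on these
# labels; a good forest should land within a few points of it.
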