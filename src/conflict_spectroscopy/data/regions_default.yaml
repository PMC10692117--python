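# Default department -> region map for the Colombian conflict analysis.
#
# The seven regions arise from overlaying the organisational structures of
# the National Army divisions, the National Police regions, and the FARC
# blocs.  The authoritative composition lives in cartographic sources;
# this file is a plausible reconstruction from prose descriptions
# (region 1 Caribbean coast, region 2 north-west, regions 3 and 7 along
# the Venezuelan border/eastern plains, region 4 on the Ecuadorian
# border, region 5 central-west, region 6 south-central).  It is
# configuration, not code: edit freely to match an authoritative source.
regions:
  1: [La Guajira, Magdalena, Atlántico, Cesar, Bolívar, Sucre, Córdoba]
  2: [Antioquia, Chocó]
  3: [Norte de Santander, Santander, Arauca, Boyacá]
  4: [Nariño, Putumayo, Cauca, Valle del Cauca]
  5: [Caldas, Risaralda, Quindío, Tolima, Huila, Cundinamarca, Bogotá]
  6: [Caquetá, Amazonas]
  7: [Meta, Casanare, Vichada, Guaviare, Guainía, Vaupés]
labels:
  1: Caribbean
  2: North-West
  3: North-East
  4: South-West
  5: Central
  6: South
  7: Eastern Plains
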