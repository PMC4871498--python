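<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
  <model id="enzyme_mass_action" name="Mass-action enzyme kinetics">
    <listOfCompartments>
      <compartment id="cell" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="E" compartment="cell" initialConcentration="0.25" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
      <species id="S" compartment="cell" initialConcentration="1" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
      <species id="C" compartment="cell" initialConcentration="0" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
      <species id="P" compartment="cell" initialConcentration="0" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="kf" value="2.718281828459045" constant="true"/>
      <parameter id="kr" value="1.6487212707001282" constant="true"/>
      <parameter id="kc" value="4.4816890703380645" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="binding" reversible="true">
        <listOfReactants>
          <speciesReference species="E" stoichiometry="1" constant="true"/>
          <speciesReference species="S" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <minus/>
              <apply>
                <times/>
                <ci>kf</ci>
                <ci>E</ci>
                <ci>S</ci>
              </apply>
              <apply>
                <times/>
                <ci>kr</ci>
                <ci>C</ci>
              </apply>
            </apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="catalysis" reversible="false">
        <listOfReactants>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="E" stoichiometry="1" constant="true"/>
          <speciesReference species="P" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <times/>
              <ci>kc</ci>
              <ci>C</ci>
            </apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
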