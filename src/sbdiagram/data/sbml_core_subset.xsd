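<?xml version="1.0" encoding="UTF-8"?>
<!--
  Subset schema for SBML Level 3 Version 1 core, covering the constructs
  this library emits: compartments, species, reactions with (modifier)
  species references, notes/annotation, and the layout package's
  listOfLayouts as a child of the model.

  The LineSegment and CubicBezier types live in this (default) namespace so
  that the conventional unprefixed xsi:type values on layout curve segments
  resolve; they derive from the layout package's curve-segment base type.
  Foreign attributes (the package "required" flags on the sbml element)
  are allowed and skipped; auxiliary markers such as complex membership
  travel inside annotation elements, whose content is not validated.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:core="http://www.sbml.org/sbml/level3/version1/core"
           xmlns:layout="http://www.sbml.org/sbml/level3/version1/layout/version1"
           targetNamespace="http://www.sbml.org/sbml/level3/version1/core"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <xs:import namespace="http://www.sbml.org/sbml/level3/version1/layout/version1"
             schemaLocation="sbml_layout_subset.xsd"/>

  <xs:complexType name="LineSegment">
    <xs:complexContent>
      <xs:extension base="layout:CurveSegment"/>
    </xs:complexContent>
  </xs:complexType>

  <xs:complexType name="CubicBezier">
    <xs:complexContent>
      <xs:extension base="layout:CurveSegment">
        <xs:sequence>
          <xs:element ref="layout:basePoint1"/>
          <xs:element ref="layout:basePoint2"/>
        </xs:sequence>
      </xs:extension>
    </xs:complexContent>
  </xs:complexType>

  <xs:simpleType name="SId">
    <xs:restriction base="xs:string">
      <xs:pattern value="[A-Za-z_][A-Za-z0-9_]*"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:simpleType name="SboTerm">
    <xs:restriction base="xs:string">
      <xs:pattern value="SBO:[0-9]{7}"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="AnyContent">
    <xs:sequence>
      <xs:any namespace="##any" processContents="skip"
              minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:anyAttribute namespace="##any" processContents="skip"/>
  </xs:complexType>

  <xs:group name="NotesAndAnnotation">
    <xs:sequence>
      <xs:element name="notes" type="core:AnyContent" minOccurs="0"/>
      <xs:element name="annotation" type="core:AnyContent" minOccurs="0"/>
    </xs:sequence>
  </xs:group>

  <xs:complexType name="Compartment">
    <xs:group ref="core:NotesAndAnnotation"/>
    <xs:attribute name="id" type="core:SId" use="required"/>
    <xs:attribute name="name" type="xs:string"/>
    <xs:attribute name="constant" type="xs:boolean" use="required"/>
    <xs:attribute name="sboTerm" type="core:SboTerm"/>
    <xs:attribute name="spatialDimensions" type="xs:double"/>
    <xs:attribute name="size" type="xs:double"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="Species">
    <xs:group ref="core:NotesAndAnnotation"/>
    <xs:attribute name="id" type="core:SId" use="required"/>
    <xs:attribute name="name" type="xs:string"/>
    <xs:attribute name="compartment" type="core:SId" use="required"/>
    <xs:attribute name="sboTerm" type="core:SboTerm"/>
    <xs:attribute name="hasOnlySubstanceUnits" type="xs:boolean" use="required"/>
    <xs:attribute name="boundaryCondition" type="xs:boolean" use="required"/>
    <xs:attribute name="constant" type="xs:boolean" use="required"/>
    <xs:attribute name="initialAmount" type="xs:double"/>
    <xs:attribute name="initialConcentration" type="xs:double"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="SpeciesReference">
    <xs:group ref="core:NotesAndAnnotation"/>
    <xs:attribute name="species" type="core:SId" use="required"/>
    <xs:attribute name="constant" type="xs:boolean" use="required"/>
    <xs:attribute name="stoichiometry" type="xs:double"/>
    <xs:attribute name="sboTerm" type="core:SboTerm"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="ModifierSpeciesReference">
    <xs:group ref="core:NotesAndAnnotation"/>
    <xs:attribute name="species" type="core:SId" use="required"/>
    <xs:attribute name="sboTerm" type="core:SboTerm"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="Reaction">
    <xs:sequence>
      <xs:element name="notes" type="core:AnyContent" minOccurs="0"/>
      <xs:element name="annotation" type="core:AnyContent" minOccurs="0"/>
      <xs:element name="listOfReactants" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="speciesReference" type="core:SpeciesReference"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfProducts" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="speciesReference" type="core:SpeciesReference"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfModifiers" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="modifierSpeciesReference"
                        type="core:ModifierSpeciesReference" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="kineticLaw" type="core:AnyContent" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="core:SId" use="required"/>
    <xs:attribute name="reversible" type="xs:boolean" use="required"/>
    <xs:attribute name="fast" type="xs:boolean"/>
    <xs:attribute name="sboTerm" type="core:SboTerm"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="Model">
    <xs:sequence>
      <xs:element name="notes" type="core:AnyContent" minOccurs="0"/>
      <xs:element name="annotation" type="core:AnyContent" minOccurs="0"/>
      <xs:element name="listOfCompartments" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="compartment" type="core:Compartment"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfSpecies" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="species" type="core:Species" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfReactions" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="reaction" type="core:Reaction" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element ref="layout:listOfLayouts" minOccurs="0"/>
    </xs:sequence>
    <xs:attribute name="id" type="core:SId"/>
    <xs:attribute name="name" type="xs:string"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:element name="sbml">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="model" type="core:Model"/>
      </xs:sequence>
      <xs:attribute name="level" type="xs:integer" use="required"/>
      <xs:attribute name="version" type="xs:integer" use="required"/>
      <xs:anyAttribute namespace="##other" processContents="skip"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
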