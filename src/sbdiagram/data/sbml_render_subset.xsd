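<?xml version="1.0" encoding="UTF-8"?>
<!--
  Subset schema for the SBML Level 3 render package (version 1), covering
  the local render information this library emits inside a layout: color
  definitions and styles with group-level stroke/fill/font attributes plus
  optional explicit shape primitives.  A leading annotation element (core
  namespace) carries the auxiliary class-selector list and is skipped.
-->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:render="http://www.sbml.org/sbml/level3/version1/render/version1"
           targetNamespace="http://www.sbml.org/sbml/level3/version1/render/version1"
           elementFormDefault="qualified"
           attributeFormDefault="qualified">

  <xs:simpleType name="RelCoord">
    <xs:restriction base="xs:string">
      <xs:pattern value="-?[0-9.]+%?"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="Rectangle">
    <xs:attribute name="x" type="render:RelCoord"/>
    <xs:attribute name="y" type="render:RelCoord"/>
    <xs:attribute name="width" type="render:RelCoord"/>
    <xs:attribute name="height" type="render:RelCoord"/>
    <xs:attribute name="rx" type="render:RelCoord"/>
    <xs:attribute name="ry" type="render:RelCoord"/>
  </xs:complexType>

  <xs:complexType name="Ellipse">
    <xs:attribute name="cx" type="render:RelCoord"/>
    <xs:attribute name="cy" type="render:RelCoord"/>
    <xs:attribute name="rx" type="render:RelCoord"/>
    <xs:attribute name="ry" type="render:RelCoord"/>
  </xs:complexType>

  <xs:complexType name="Group">
    <xs:choice minOccurs="0" maxOccurs="unbounded">
      <xs:element name="rectangle" type="render:Rectangle"/>
      <xs:element name="ellipse" type="render:Ellipse"/>
    </xs:choice>
    <xs:attribute name="stroke" type="xs:string"/>
    <xs:attribute name="stroke-width" type="xs:double"/>
    <xs:attribute name="fill" type="xs:string"/>
    <xs:attribute name="font-family" type="xs:string"/>
    <xs:attribute name="font-size" type="xs:double"/>
    <xs:attribute name="font-weight" type="xs:string"/>
    <xs:attribute name="font-style" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="Style">
    <xs:sequence>
      <xs:any namespace="##other" processContents="skip" minOccurs="0"/>
      <xs:element name="g" type="render:Group"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="idList" type="xs:string"/>
    <xs:attribute name="roleList" type="xs:string"/>
    <xs:attribute name="typeList" type="xs:string"/>
    <xs:anyAttribute namespace="##other" processContents="skip"/>
  </xs:complexType>

  <xs:complexType name="ColorDefinition">
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="value" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="RenderInformation">
    <xs:sequence>
      <xs:element name="listOfColorDefinitions" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="colorDefinition" type="render:ColorDefinition"
                        maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfStyles" minOccurs="0">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="style" type="render:Style" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="name" type="xs:string"/>
    <xs:attribute name="programName" type="xs:string"/>
    <xs:attribute name="programVersion" type="xs:string"/>
    <xs:attribute name="backgroundColor" type="xs:string"/>
  </xs:complexType>

  <xs:element name="listOfRenderInformation">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="renderInformation" type="render:RenderInformation"
                    maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="versionMajor" type="xs:integer"/>
      <xs:attribute name="versionMinor" type="xs:integer"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
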